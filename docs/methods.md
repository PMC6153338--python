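# Methods

## Scope and data model

The pipeline analyzes two kinds of records. A *spike train* is a strictly
increasing sequence of spike times (seconds from recording onset, half-open
window [0, duration)), with metadata for treatment group, estrous-cycle
stage and soma location; recordings of this kind typically run 40–90 min
per cell. A *voltage sweep* is a uniformly sampled current-clamp trace
(mV) around a depolarizing current step. All times are seconds, all
logarithms base 10; duplicate spike times are rejected at load because a
zero ISI has no logarithm (acquisition at 12 kHz cannot produce true
duplicates).

## Burst-threshold optimization on the ISI return map

Each interior spike of a train maps to the point
(log₁₀ ISI-before, log₁₀ ISI-after). A candidate threshold θ partitions
the map into quadrants at t = log₁₀ θ: C1 (x<t, y<t), C2 (x≥t, y<t),
C3 (x≥t, y≥t), C4 (x<t, y≥t); points exactly on the boundary go to the
long side so the partition is deterministic. The objective is the summed
squared Euclidean distance of every point to its quadrant centroid (empty
and singleton quadrants contribute zero); the optimal θ is the argmin over
the candidate grid, ties broken toward the smallest candidate
(conservative: shorter bursts).

**Candidate grid.** Candidates are de-duplicated quantiles of the
observed ISI distribution, 1%–99% in 0.1% steps (981 values), with an
explicit log-spaced grid available as a config override. Quantile
candidates make the search scale-covariant: rescaling time rescales the
optimum exactly. The step matters: a strongly bursting train has an empty
interval between its intraburst-ISI and interburst-gap modes whose width
in rank space is ~1/n_ISI. A grid step coarser than that (e.g. 1% steps
on a 400-ISI train) can skip the interval entirely, leaving only candidates
just inside one mode; the argmin then sits a hair below the largest
intraburst ISI or above the smallest gap, splitting or merging a few
bursts, and which side wins varies neuron to neuron. With 0.1% steps the
empty interval always contains a candidate for trains up to ~1000 ISIs,
and on the bursting preset the optimum falls strictly between the largest
intraburst ISI and the smallest gap in 100/100 trains. The search is
implemented as a sorted sweep (within-cluster SS from cumulative
coordinate sums via the identity SS = Σ‖p‖² − Σ_q ‖S_q‖²/n_q), costing
O((n + C) log n) rather than O(n·C).

## Firing-pattern classification

The cascade assigns exactly one label per neuron:

1. **quiet** — fewer than `min_pairs` = 10 return-map points (i.e. < 12
   spikes) or mean rate < 0.01 Hz. Both limits are configurable; 10 pairs
   is the minimum for meaningful quadrant statistics, and 0.01 Hz matches
   how near-silent cells are reported in this literature.
2. **bursting** — at the optimal θ, C1 holds at least twice as many points
   as C2 and as C4, and at least five times as many as C3.
3. **tonic** — not bursting, and every nonempty quadrant centroid has both
   coordinates below log₁₀(1 s) = 0. Empty quadrants are ignored (their
   centroid is undefined).
4. **irregular** — otherwise.

The bursting decision is invariant under uniform time rescaling (the
quantile grid rescales with the data); the tonic decision is deliberately
not, since the 1-s limit is absolute. The quadrant semantics follow the
geometry of the return map: C2 (long-before, short-after) are burst-onset
spikes and C4 (short-before, long-after) burst-offset spikes.

## Burst segmentation and properties

At threshold θ, bursts are maximal runs of consecutive spikes whose
internal ISIs are all strictly below θ (consistent with the ≥ θ "long"
side of the quadrant rule), kept when they contain ≥ 4 spikes. Properties:
duration (first-to-last spike), spikes per burst, intraburst rate
(n−1)/duration — a rate of intervals, matching a duration measured
first-to-last — and interburst interval, measured from the last spike of
one burst to the first spike of the next, ignoring any non-burst spikes
between them.

For group comparisons each neuron contributes at most 100 bursts, drawn
without replacement from a per-neuron RNG stream keyed by
(global seed, CRC32 of neuron id), so cohort composition cannot perturb
any one neuron's draw; neurons with ≤ 100 bursts contribute all of them.

## Group statistics

Per group and property, the subsampled per-neuron vectors are concatenated
(no further weighting — the 100-burst cap is the guard against dominance
by high-burst cells) and compared pairwise between groups with the
two-sample KS statistic; p-values are exact when n_a·n_b ≤ 10,000 and
asymptotic otherwise, which is the standard regime for pooled samples of
hundreds. Significance uses the stringent p < 0.001 criterion with no
multiple-testing correction, the criterion itself being the guard.
Pattern proportions use a two-sided Fisher's exact test computed by exact
rational hypergeometric enumeration (sum of the conditional probabilities
of all tables no more probable than the observed one); exact arithmetic
makes point-probability ties unambiguous. Zero-margin tables return p = 1
with a flag.

**Calibration.** On null cohorts (both groups drawn from one bursting
preset; 2 × 5 neurons, ~70 bursts each) the duration-KS rejection rate at
nominal α = 0.05 sits inside the exact binomial 99% interval over 500
simulated cohorts, and no rejections occur at α = 0.001. Spikes per burst
is integer-valued; KS with heavily tied data is conservative (observed
≈ 0.5% rejection at nominal 5%), so calibration statements are made on the
continuous properties. With the mean burst length doubled in one group
(15 cells/group, ≤ 100 bursts/cell), duration and spikes-per-burst
comparisons reach p < 0.001 essentially always.

## Current-clamp analytics

dV/dt is computed by centred differences on the raw sampled trace (no
smoothing by default; a sample rate below 10 kHz triggers a warning). APs
are located as voltage peaks above −20 mV with ≥ 20 mV prominence; for
each, the threshold is the voltage at the first sample of the contiguous
upstroke run with dV/dt ≥ 5 V/s — a direct phase-plot read-off, not
interpolated between samples. An event spans from its threshold crossing
to the next event's crossing or a 10-ms post-peak window, whichever is
earlier. FWHM is measured at half the threshold-to-peak amplitude with
linear interpolation at both crossings; AHP is reported as a positive
depth below threshold (a voltage, in mV), with its latency from the
threshold crossing; max rise/decay slopes are centred-difference extrema
within the event. Events truncated by the sweep edge are completed as far
as possible and flagged partial.

Evoked rate is the spike count inside the step window over the window
duration; latency is first threshold crossing minus step onset (undefined,
flagged NaN, for silent sweeps); first-10 statistics use the first 10
evoked ISIs (all ISIs when fewer than 11 spikes). F-I AUC is the composite
trapezoid over the current axis, exactly linear and interval-additive in
the rate vector.

Passive properties follow the two-resistor whole-cell test-pulse circuit:
a ΔV = 5 mV step drives I(t) = I_ss + (I_peak − I_ss)e^(−t/τ) with
I_peak = ΔV/Rs, I_ss = ΔV/(Rs+Rin), τ = Cm·RsRin/(Rs+Rin). The transient
amplitude is extrapolated to the step onset by a mono-exponential fit so
the finite sample rate does not clip the peak; Rin comes from the
steady-state mean of the last fifth of the step, and Cm = τ(1/Rs + 1/Rin).
Non-decaying transients set a fit-failure flag and fail QC. QC passes iff
Rs < 20 MΩ and Rin > 500 MΩ. On ideal simulated cells the estimators are
exact; with 1-pA current noise the Rin error is ~1.5% RMS (the steady-state
current is only a few pA), well inside 5%.

## Synthetic data

The generators emulate the firing regimes of recorded GnRH neurons (mean
rates 0–3.8 Hz, ISIs spanning tens of milliseconds to tens of seconds):

* **bursting** — alternating renewal: spikes per burst 4 + Poisson(2)
  (mean 6), intraburst ISIs 50 ms with 10% jitter, interburst gaps
  log-normal with mean 8 s and log-sd 0.5 (heavy-tailed, as interval
  distributions plotted on log axes are), over 600 s;
* **tonic** — 5 Hz regular firing with 5% ISI jitter (all ISIs ≪ 1 s);
* **irregular** — homogeneous Poisson at 0.5 Hz;
* **quiet** — Poisson at 0.005 Hz over 3600 s.

Bursts truncated by the recording window keep only in-window spikes.
Cohort generation derives per-neuron seeds from
(master seed, group index, neuron index); no global RNG state is used.

Current-clamp sweeps are piecewise-analytic templates on an RC charging
baseline (rest −73 mV, junction-corrected scale): a 2 V/s approach ramp
ends exactly at the configured threshold voltage, followed by a
quarter-sine upstroke (initial slope ≈ 210 V/s, far above the 5 V/s
criterion) to +10 mV, a half-cosine downstroke to an AHP 25 mV below
threshold, and exponential recovery. The first 5 V/s crossing of the
continuous waveform is therefore at the configured threshold exactly,
giving closed-form ground truth for the detector; at the default 20-kHz
sample rate and 0.2-mV noise the detector recovers it to well under 1 mV.
Evoked rate is linear in current above rheobase (default gain 0.5 Hz/pA,
rheobase 20 pA, 1-s steps in 10-pA increments), so the continuous F-I
area has the closed form gain·(I_max − rheobase)²/2. The step duration of
the F-I protocol defaults to 1 s (configurable).

**What the generators do not emulate:** slow nonstationarity within a
recording (drifting rates, state switches), correlated burst structure,
conductance-based spike shapes, electrode artifacts, and seal/access
degradation over time. Passing tests therefore demonstrate correctness of
the analysis chain under the stated statistical models, not robustness to
every pathology of real recordings.

## Problem sizes and determinism

The test suite and the acceptance script use: 800 trains (200 per class)
for label recovery; 200 bursting trains for threshold placement; 500 null
cohorts (2 × 5 neurons) for KS calibration and 20 effect cohorts
(2 × 15 neurons) for power; 10 noise seeds for AP-threshold and passive
recovery; 11-step F-I families. These sizes give binomial/Monte-Carlo
precision comfortably finer than the thresholds being checked. Every
stochastic step flows from an explicit seed, and identical configuration
plus seed yields byte-identical report files.

## Known limitations

* The centroid-distance objective is a 4-cluster within-sum-of-squares on
  a constrained (axis-aligned, shared-threshold) partition; for weakly
  bimodal trains the minimum can be shallow and the chosen θ sensitive to
  a few points. Diagnostics (full candidate/distance vectors) are
  returned for inspection.
* Pooled KS treats bursts as exchangeable across neurons; with strong
  per-neuron heterogeneity the effective sample size is smaller than the
  pooled count and p-values become anti-conservative. The 100-burst cap
  bounds, but does not remove, this effect.
* The tonic rule's absolute 1-s limit is intentionally not
  scale-invariant; rescaled data must be expressed in seconds.
* AP threshold is reported at sample resolution (no sub-sample
  interpolation); at ≥ 20 kHz this quantization is ≪ 1 mV on the upstroke.
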