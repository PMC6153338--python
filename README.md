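# gnburst

Spike-train and intrinsic-excitability analysis for GnRH (gonadotropin-
releasing hormone) neuron recordings, built as a tested, reusable pipeline
and exercised end-to-end on synthetic cohorts with known ground truth.

GnRH neurons fire in bursts that drive pulsatile hormone release, and their
firing patterns shift across the estrous cycle and in disease models such
as intrahippocampal-kainate temporal-lobe epilepsy. This package implements
the analysis chain used to quantify those changes from loose-patch spike
trains and whole-cell current-clamp sweeps:

1. **ISI return map & burst threshold.** Each spike contributes a point
   (log₁₀ ISIₙ, log₁₀ ISIₙ₊₁) — the interval before vs. after it. A
   candidate burst ISI threshold θ splits the map into quadrants C1–C4
   (lower-left = within burst, lower-right = burst onset, upper-right =
   isolated, upper-left = burst offset). The optimal θ minimizes
   Σ_q Σ_{p∈q} ‖p − c_q‖², the summed squared distance of points to their
   quadrant centroids, over a grid of ISI-quantile candidates.
2. **Firing-pattern classification.** quiet (minimum-activity gate:
   < 10 return-map points or mean rate < 0.01 Hz) → bursting
   (n₁ ≥ 2n₂, n₁ ≥ 2n₄, n₁ ≥ 5n₃ at the optimal θ) → tonic (every
   nonempty quadrant centroid at ISIs < 1 s) → irregular otherwise.
3. **Burst properties.** Bursts are maximal runs of ≥ 4 spikes with
   internal ISIs < θ; properties are duration, spikes per burst,
   intraburst rate (n−1)/duration, and interburst interval. Up to 100
   bursts per neuron (seeded subsample) are pooled per group into
   cumulative probability distributions, compared between groups with
   two-sample Kolmogorov–Smirnov tests at p < 0.001; pattern proportions
   are compared with exact two-sided Fisher tests.
4. **Intrinsic excitability.** AP threshold is read off the dV/dt phase
   plot (first upstroke sample with dV/dt ≥ 5 V/s); kinetics include FWHM,
   AHP depth and latency, and max rise/decay slopes. The F-I curve (evoked
   rate vs. 10-pA current steps) is summarized by trapezoidal AUC.
   Passive properties come from a 5-mV voltage-clamp test pulse, with QC
   gates Rs < 20 MΩ and Rin > 500 MΩ; voltages carry a 13-mV liquid-
   junction-potential correction.

A seeded synthetic-data module generates bursting / tonic / irregular /
quiet trains, multi-group cohorts, and current-clamp sweeps with analytic
spike templates, so every stage can be validated against ground truth.

## Worked example

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_classify_patterns.py
```

prints the recovery of generated labels on a 40-neuron four-preset cohort:

```
confusion (rows = generated, columns = recovered):
label         bursting  irregular  quiet  tonic
true_pattern
bursting            10          0      0      0
irregular            0         10      0      0
quiet                0          0     10      0
tonic                0          0      0     10
overall recovery accuracy: 100.0% (40 neurons)
```

and `python analysis/04_group_comparisons.py` runs the KS battery on a
two-group cohort whose second group doubles the mean burst length:

```
           property  n_a  n_b        D        p  significant
           duration 1059 1093 0.836806 0.000000         True
   spikes_per_burst 1059 1093 0.837809 0.000000         True
    intraburst_rate 1059 1093 0.112921 0.000002         True
interburst_interval 1044 1078 0.040495 0.340629        False
```

Duration and spikes per burst separate with D ≈ 0.84; the untouched
interburst-interval distribution does not. (Intraburst rate shows a small
but real distributional change: longer bursts average over more jittered
ISIs, narrowing the rate distribution.) The same stages are available from
the command line: `gnburst simulate | classify | compare | excitability`.

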