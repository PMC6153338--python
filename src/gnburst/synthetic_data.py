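"""Seeded generators for spike trains, cohorts, and current-clamp sweeps.

These emulate the regimes seen in GnRH neuron recordings so every pipeline
stage can be exercised against known ground truth without real data:

* **bursting** — an alternating-renewal process: bursts of a drawn spike
  count (shifted Poisson, minimum 4) fired at a fixed intraburst rate with
  mild ISI jitter, separated by log-normal interburst gaps (heavy-tailed
  intervals, as real interval distributions plotted on log axes are);
* **tonic** — jittered regular firing with every ISI well below 1 s;
* **irregular** — a homogeneous Poisson process;
* **quiet** — a Poisson process at ≤ 0.01 Hz.

Current-clamp sweeps are piecewise-analytic spike templates on an RC
charging baseline: the template approaches threshold on a slow (2 V/s)
ramp and then rises as a quarter-sine, so the first 5 V/s phase-plot
crossing sits at the configured threshold voltage exactly — the detector
can be scored against closed-form truth.  Passive test pulses follow the
two-resistor RC pipette circuit in closed form.

All randomness flows from explicit seeds; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import CycleStage, Location, SpikeTrain, Treatment
from .excitability import TestPulseRecording, VoltageSweep
from .pattern_classifier import Pattern

__all__ = [
    "TrainGenParams",
    "TrainTruth",
    "CohortSpec",
    "CellParams",
    "STANDARD_PRESETS",
    "generate_train",
    "generate_train_with_truth",
    "generate_cohort",
    "generate_sweep",
    "generate_fi_family",
    "generate_test_pulse",
]


@dataclass(frozen=True)
class TrainGenParams:
    """Parameters of one synthetic spike train.

    Only the block matching ``pattern`` is used.  Defaults are the standard
    recoverable presets: well-separated firing regimes inside the ranges
    seen in the recordings (mean rates 0–3.8 Hz, ISIs from tens of
    milliseconds to tens of seconds).
    """

    pattern: Pattern
    duration_s: float = 600.0
    seed: int = 0
    # bursting
    intraburst_rate_hz: float = 20.0
    intraburst_jitter_cv: float = 0.1
    spikes_per_burst_mean: float = 6.0
    interburst_interval_mean_s: float = 8.0
    interburst_dispersion: float = 0.5  # sigma of log interval
    # tonic
    tonic_rate_hz: float = 5.0
    tonic_jitter_cv: float = 0.05
    # irregular
    irregular_rate_hz: float = 0.5
    # quiet
    quiet_rate_hz: float = 0.005

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.pattern == Pattern.BURSTING:
            if self.spikes_per_burst_mean < 4:
                raise ValueError("recoverable bursting presets need ≥ 4 spikes/burst")
            if 1.0 / self.intraburst_rate_hz >= self.interburst_interval_mean_s:
                raise ValueError(
                    "intraburst ISI must be shorter than the mean interburst gap"
                )
        if self.pattern == Pattern.QUIET and self.quiet_rate_hz > 0.01:
            raise ValueError("quiet preset rate must be ≤ 0.01 Hz")


@dataclass(frozen=True)
class TrainTruth:
    """Generator-side ground truth attached to a synthetic train."""

    pattern: Pattern
    max_intraburst_isi_s: float = float("nan")
    min_interburst_gap_s: float = float("nan")
    n_bursts: int = 0


STANDARD_PRESETS: dict[Pattern, TrainGenParams] = {
    Pattern.BURSTING: TrainGenParams(pattern=Pattern.BURSTING),
    Pattern.TONIC: TrainGenParams(pattern=Pattern.TONIC),
    Pattern.IRREGULAR: TrainGenParams(pattern=Pattern.IRREGULAR),
    Pattern.QUIET: TrainGenParams(pattern=Pattern.QUIET, duration_s=3600.0),
}


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _make_train(times: np.ndarray, params: TrainGenParams, neuron_id: str) -> SpikeTrain:
    # enforce strict increase: drop numerically coincident spikes
    if times.size > 1:
        keep = np.concatenate([[True], np.diff(times) > 0])
        times = times[keep]
    return SpikeTrain(neuron_id=neuron_id, spike_times=times, duration=params.duration_s)


def generate_train_with_truth(
    params: TrainGenParams, neuron_id: str = "synthetic"
) -> tuple[SpikeTrain, TrainTruth]:
    """Generate one train plus its generator-side ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    if params.pattern == Pattern.BURSTING:
        times: list[float] = []
        intra_isis: list[float] = []
        gaps: list[float] = []
        mean_isi = 1.0 / params.intraburst_rate_hz
        sigma = params.interburst_dispersion
        mu = np.log(params.interburst_interval_mean_s) - sigma**2 / 2.0
        t = float(rng.uniform(0, params.interburst_interval_mean_s / 4))
        n_bursts = 0
        while t < params.duration_s:
            n_spk = 4 + int(rng.poisson(params.spikes_per_burst_mean - 4))
            burst_times = [t]
            for _ in range(n_spk - 1):
                isi = mean_isi * max(
                    0.1, 1.0 + params.intraburst_jitter_cv * rng.standard_normal()
                )
                burst_times.append(burst_times[-1] + isi)
                intra_isis.append(isi)
            in_window = [bt for bt in burst_times if bt < params.duration_s]
            times.extend(in_window)
            if len(in_window) == n_spk:
                n_bursts += 1
            gap = float(np.exp(mu + sigma * rng.standard_normal()))
            gaps.append(gap)
            t = burst_times[-1] + gap
        truth = TrainTruth(
            pattern=Pattern.BURSTING,
            max_intraburst_isi_s=max(intra_isis) if intra_isis else float("nan"),
            min_interburst_gap_s=min(gaps) if gaps else float("nan"),
            n_bursts=n_bursts,
        )
        return _make_train(np.asarray(times), params, neuron_id), truth

    if params.pattern == Pattern.TONIC:
        mean_isi = 1.0 / params.tonic_rate_hz
        n_max = int(params.duration_s / mean_isi * 1.5) + 10
        jitter = 1.0 + params.tonic_jitter_cv * rng.standard_normal(n_max)
        isis = mean_isi * np.clip(jitter, 0.1, None)
        times = np.cumsum(isis)
        times = times[times < params.duration_s]
        return (
            _make_train(times, params, neuron_id),
            TrainTruth(pattern=Pattern.TONIC),
        )

    if params.pattern == Pattern.IRREGULAR:
        times = _poisson_times(rng, params.irregular_rate_hz, params.duration_s)
        return _make_train(times, params, neuron_id), TrainTruth(pattern=Pattern.IRREGULAR)

    times = _poisson_times(rng, params.quiet_rate_hz, params.duration_s)
    return _make_train(times, params, neuron_id), TrainTruth(pattern=Pattern.QUIET)


def generate_train(params: TrainGenParams, neuron_id: str = "synthetic") -> SpikeTrain:
    """Generate one synthetic spike train (deterministic given the seed)."""
    return generate_train_with_truth(params, neuron_id)[0]


@dataclass(frozen=True)
class CohortSpec:
    """A multi-group synthetic cohort: (group_key, n_neurons, params) triples."""

    groups: tuple[tuple[tuple[str, str], int, TrainGenParams], ...]
    master_seed: int = 0


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[SpikeTrain, TrainTruth, tuple[str, str]]]:
    """Generate a labelled cohort; per-neuron seeds derive from
    (master_seed, group index, neuron index)."""
    out = []
    for g_idx, (group_key, n_neurons, params) in enumerate(spec.groups):
        if n_neurons < 1:
            raise ValueError("each group needs at least one neuron")
        for k in range(n_neurons):
            seed = int(
                np.random.SeedSequence(
                    [spec.master_seed, g_idx, k]
                ).generate_state(1)[0]
                % (2**31)
            )
            nid = f"{group_key[0]}_{group_key[1]}_{k:03d}"
            neuron_params = replace(params, seed=seed)
            train, truth = generate_train_with_truth(neuron_params, neuron_id=nid)
            treatment = Treatment(group_key[0]) if group_key[0] in Treatment._value2member_map_ else Treatment.SALINE
            stage = CycleStage(group_key[1]) if group_key[1] in CycleStage._value2member_map_ else CycleStage.NONE
            train = SpikeTrain(
                neuron_id=nid,
                spike_times=train.spike_times,
                duration=train.duration,
                treatment=treatment,
                cycle_stage=stage,
                location=Location.UNKNOWN,
            )
            out.append((train, truth, group_key))
    return out


@dataclass(frozen=True)
class CellParams:
    """A simulated current-clamp cell with analytic spike templates.

    ``threshold_mv`` is the exact voltage of the template's first 5 V/s
    phase-plot crossing: the spike approaches it on a 2 V/s ramp and leaves
    it on a quarter-sine upstroke whose initial slope is far above
    criterion.  Evoked rate is linear in current above rheobase with slope
    ``gain_hz_per_pa``.  Passive values parameterize both the subthreshold
    charging and the voltage-clamp test pulse.
    """

    threshold_mv: float = -44.0
    peak_mv: float = 10.0
    ahp_depth_mv: float = 25.0
    rheobase_pa: float = 20.0
    gain_hz_per_pa: float = 0.5
    latency_s: float = 0.015
    baseline_mv: float = -73.0
    plateau_mv: float = -60.0
    ramp_slope_mv_per_ms: float = 2.0
    t_rise_ms: float = 0.4
    t_fall_ms: float = 1.2
    ahp_tau_ms: float = 3.0
    rs_mohm: float = 10.0
    rin_mohm: float = 800.0
    cm_pf: float = 16.0
    sample_rate_hz: float = 20_000.0
    noise_sd_mv: float = 0.2
    pre_s: float = 0.1
    step_dur_s: float = 1.0
    post_s: float = 0.1

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant Rin·Cm in ms (MΩ·pF = μs)."""
        return self.rin_mohm * self.cm_pf / 1e3


def _paint_spike(
    v: np.ndarray, sr: float, t0_s: float, cell: CellParams
) -> None:
    """Overwrite the trace with one spike template anchored at threshold time t0."""
    dt_ms = 1e3 / sr
    thr, peak = cell.threshold_mv, cell.peak_mv
    ahp = thr - cell.ahp_depth_mv
    i0 = int(round(t0_s * sr))
    n = v.size

    # approach ramp: rising line ending at (t0, thr); splice where it
    # exceeds the existing trace so the junction is continuous
    ramp_span = int(round(25.0 / dt_ms))  # generous backward window
    lo = max(0, i0 - ramp_span)
    idx = np.arange(lo, min(i0, n))
    if idx.size:
        ramp_v = thr - cell.ramp_slope_mv_per_ms * (i0 - idx) * dt_ms
        take = ramp_v > v[idx]
        v[idx[take]] = ramp_v[take]

    # quarter-sine upstroke threshold → peak
    n_rise = max(2, int(round(cell.t_rise_ms / dt_ms)))
    idx = np.arange(i0, min(i0 + n_rise + 1, n))
    if idx.size:
        phase = (idx - i0) * dt_ms / cell.t_rise_ms
        v[idx] = thr + (peak - thr) * np.sin(np.pi / 2 * np.clip(phase, 0, 1))

    # half-cosine downstroke peak → AHP minimum
    i_peak = i0 + n_rise
    n_fall = max(2, int(round(cell.t_fall_ms / dt_ms)))
    idx = np.arange(i_peak, min(i_peak + n_fall + 1, n))
    if idx.size:
        phase = (idx - i_peak) * dt_ms / cell.t_fall_ms
        v[idx] = ahp + (peak - ahp) * (1 + np.cos(np.pi * np.clip(phase, 0, 1))) / 2

    # exponential recovery AHP → plateau
    i_ahp = i_peak + n_fall
    n_rec = int(round(8 * cell.ahp_tau_ms / dt_ms))
    idx = np.arange(i_ahp, min(i_ahp + n_rec, n))
    if idx.size:
        t_ms = (idx - i_ahp) * dt_ms
        v[idx] = cell.plateau_mv + (ahp - cell.plateau_mv) * np.exp(
            -t_ms / cell.ahp_tau_ms
        )


def generate_sweep(
    cell: CellParams, current_step_pa: float, seed: int = 0
) -> tuple[VoltageSweep, dict]:
    """One current-step sweep plus ground truth (threshold, spike times, rate)."""
    sr = cell.sample_rate_hz
    n_total = int(round((cell.pre_s + cell.step_dur_s + cell.post_s) * sr))
    onset, offset = cell.pre_s, cell.pre_s + cell.step_dur_s
    t = np.arange(n_total) / sr
    v = np.full(n_total, cell.baseline_mv)

    # subthreshold RC charge toward the plateau during the step, discharge after
    tau_s = cell.tau_m_ms / 1e3
    in_step = (t >= onset) & (t < offset)
    v[in_step] = cell.plateau_mv + (cell.baseline_mv - cell.plateau_mv) * np.exp(
        -(t[in_step] - onset) / tau_s
    )
    after = t >= offset
    v_off = cell.plateau_mv + (cell.baseline_mv - cell.plateau_mv) * np.exp(
        -(offset - onset) / tau_s
    )
    v[after] = cell.baseline_mv + (v_off - cell.baseline_mv) * np.exp(
        -(t[after] - offset) / tau_s
    )

    rate = cell.gain_hz_per_pa * max(0.0, current_step_pa - cell.rheobase_pa)
    spike_times: list[float] = []
    if rate > 0:
        tail_s = (cell.t_rise_ms + cell.t_fall_ms + 1.0) / 1e3
        t_spk = onset + cell.latency_s
        while t_spk + tail_s < offset:
            spike_times.append(t_spk)
            t_spk += 1.0 / rate
    for t0 in spike_times:
        _paint_spike(v, sr, t0, cell)

    rng = np.random.default_rng(seed)
    if cell.noise_sd_mv > 0:
        v = v + rng.normal(0.0, cell.noise_sd_mv, size=n_total)

    sweep = VoltageSweep(
        sample_rate_hz=sr,
        voltage_mv=v,
        current_step_pa=float(current_step_pa),
        step_onset_s=onset,
        step_offset_s=offset,
        junction_corrected=True,
    )
    truth = {
        "threshold_mv": cell.threshold_mv,
        "spike_times_s": np.asarray(spike_times),
        "n_spikes": len(spike_times),
        "true_rate_hz": rate,
        "measured_rate_hz": len(spike_times) / cell.step_dur_s,
        "peak_mv": cell.peak_mv,
        "ahp_depth_mv": cell.ahp_depth_mv,
        "latency_s": cell.latency_s,
    }
    return sweep, truth


def generate_fi_family(
    cell: CellParams,
    currents_pa: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[VoltageSweep], dict]:
    """A 10-pA current-step family (default 0–100 pA) with closed-form AUC truth.

    For a linear-gain cell the continuous-rate F-I area is
    gain·(I_max − rheobase)²/2 above rheobase.
    """
    if currents_pa is None:
        currents_pa = np.arange(0.0, 101.0, 10.0)
    currents_pa = np.asarray(currents_pa, dtype=float)
    sweeps = []
    truths = []
    for k, i_pa in enumerate(currents_pa):
        sw, tr = generate_sweep(cell, i_pa, seed=int(
            np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)
        ))
        sweeps.append(sw)
        truths.append(tr)
    i_max = currents_pa.max()
    analytic_auc = (
        cell.gain_hz_per_pa * max(0.0, i_max - cell.rheobase_pa) ** 2 / 2.0
    )
    truth = {
        "analytic_auc_hz_pa": analytic_auc,
        "per_sweep": truths,
        "currents_pa": currents_pa,
    }
    return sweeps, truth


def generate_test_pulse(
    cell: CellParams,
    dv_mv: float = 5.0,
    sample_rate_hz: float = 100_000.0,
    noise_sd_pa: float = 1.0,
    seed: int = 0,
) -> tuple[TestPulseRecording, dict]:
    """Voltage-clamp test-pulse current for the two-resistor RC pipette circuit.

    I(t) = I_ss + (I_peak − I_ss)·exp(−t/τ) with I_peak = ΔV/Rs,
    I_ss = ΔV/(Rs+Rin) and τ = Cm·Rs·Rin/(Rs+Rin).  ΔV in mV over MΩ gives
    nA, reported in pA.
    """
    onset_s, offset_s, total_s = 0.002, 0.012, 0.015
    n = int(round(total_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    i_peak = 1e3 * dv_mv / cell.rs_mohm  # pA
    i_ss = 1e3 * dv_mv / (cell.rs_mohm + cell.rin_mohm)
    r_par = cell.rs_mohm * cell.rin_mohm / (cell.rs_mohm + cell.rin_mohm)
    tau_s = r_par * cell.cm_pf * 1e-6  # MΩ·pF = μs
    current = np.zeros(n)
    in_step = (t >= onset_s) & (t < offset_s)
    current[in_step] = i_ss + (i_peak - i_ss) * np.exp(-(t[in_step] - onset_s) / tau_s)
    rng = np.random.default_rng(seed)
    if noise_sd_pa > 0:
        current = current + rng.normal(0.0, noise_sd_pa, size=n)
    rec = TestPulseRecording(
        sample_rate_hz=sample_rate_hz,
        current_pa=current,
        step_onset_s=onset_s,
        step_offset_s=offset_s,
        dv_mv=dv_mv,
    )
    truth = {
        "rs_mohm": cell.rs_mohm,
        "rin_mohm": cell.rin_mohm,
        "cm_pf": cell.cm_pf,
        "tau_ms": tau_s * 1e3,
    }
    return rec, truth
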