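"""Current-clamp analytics: AP detection, kinetics, F-I curves, passive QC.

Action potentials are detected on depolarizing current-step sweeps and
their threshold read off the phase plot: the membrane voltage at the first
sample of the upstroke where the centred-difference dV/dt reaches 5 V/s.
Kinetics follow the standard definitions — FWHM at half the
threshold-to-peak amplitude (linearly interpolated at the crossings), AHP
as the positive depth of the post-peak minimum below threshold, and maximum
rise/decay slopes from centred differences inside the event window.

The frequency–current (F-I) relation is the evoked rate per current step,
summarized by trapezoidal area under the curve (Hz·pA).  Passive properties
come from a 5-mV voltage-clamp test pulse: series resistance from the peak
capacitive transient (amplitude extrapolated to step onset by an
exponential fit), input resistance from the steady-state current, membrane
time constant from the transient decay, and capacitance from
τ = Cm·(Rs·Rin/(Rs+Rin)).  Recordings only pass QC with Rs < 20 MΩ and
Rin > 500 MΩ.  Recorded voltages carry a liquid-junction-potential
correction (13 mV subtracted), applied exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal

__all__ = [
    "VoltageSweep",
    "APEvent",
    "FICurve",
    "PassiveProperties",
    "TestPulseRecording",
    "EvokedResponse",
    "apply_junction_correction",
    "detect_aps",
    "ap_kinetics",
    "evoked_rate",
    "build_fi_curve",
    "fi_auc",
    "passive_from_step",
]

DVDT_THRESHOLD_V_PER_S = 5.0
JUNCTION_MV = 13.0
QC_RS_MAX_MOHM = 20.0
QC_RIN_MIN_MOHM = 500.0


@dataclass(frozen=True)
class VoltageSweep:
    """One current-clamp sweep: uniformly sampled membrane voltage (mV)."""

    sample_rate_hz: float
    voltage_mv: np.ndarray
    current_step_pa: float
    step_onset_s: float
    step_offset_s: float
    junction_corrected: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage_mv, dtype=float)
        object.__setattr__(self, "voltage_mv", v)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        dur = v.size / self.sample_rate_hz
        if not (0 <= self.step_onset_s < self.step_offset_s <= dur + 1e-9):
            raise ValueError("current step window must lie within the sweep")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.voltage_mv.size) / self.sample_rate_hz

    def dvdt_v_per_s(self) -> np.ndarray:
        """Centred-difference dV/dt in V/s (mV/ms); one-sided at the edges."""
        return np.gradient(self.voltage_mv, 1e3 / self.sample_rate_hz)


@dataclass(frozen=True)
class APEvent:
    """One detected action potential and (once completed) its kinetics."""

    threshold_mv: float
    threshold_t_s: float
    peak_mv: float
    peak_t_s: float
    threshold_idx: int = -1
    peak_idx: int = -1
    end_idx: int = -1
    fwhm_ms: float = float("nan")
    ahp_amplitude_mv: float = float("nan")
    time_to_ahp_ms: float = float("nan")
    max_rise_slope_v_per_s: float = float("nan")
    max_decay_slope_v_per_s: float = float("nan")
    partial: bool = False


@dataclass(frozen=True)
class EvokedResponse:
    """Evoked-firing summary of one step sweep."""

    rate_hz: float
    n_spikes: int
    latency_s: float = float("nan")
    mean_isi_first10_ms: float = float("nan")
    mean_inst_freq_first10_hz: float = float("nan")


@dataclass(frozen=True)
class FICurve:
    currents_pa: np.ndarray
    evoked_rate_hz: np.ndarray

    def __post_init__(self) -> None:
        i = np.asarray(self.currents_pa, dtype=float)
        r = np.asarray(self.evoked_rate_hz, dtype=float)
        if i.size != r.size:
            raise ValueError("currents and rates must align")
        if np.any(np.diff(i) <= 0):
            raise ValueError("currents must be strictly increasing (no duplicates)")
        object.__setattr__(self, "currents_pa", i)
        object.__setattr__(self, "evoked_rate_hz", r)

    @property
    def auc(self) -> float:
        """Trapezoidal area under the F-I curve, in Hz·pA."""
        return fi_auc(self.currents_pa, self.evoked_rate_hz)


@dataclass(frozen=True)
class PassiveProperties:
    series_resistance_mohm: float
    input_resistance_mohm: float
    capacitance_pf: float
    tau_ms: float
    fit_failed: bool = False

    @property
    def qc_pass(self) -> bool:
        return (
            not self.fit_failed
            and self.series_resistance_mohm < QC_RS_MAX_MOHM
            and self.input_resistance_mohm > QC_RIN_MIN_MOHM
        )


@dataclass(frozen=True)
class TestPulseRecording:
    """Voltage-clamp test pulse: pipette current (pA) around a dv step."""

    sample_rate_hz: float
    current_pa: np.ndarray
    step_onset_s: float
    step_offset_s: float
    dv_mv: float = 5.0


def apply_junction_correction(
    sweep: VoltageSweep, correction_mv: float = JUNCTION_MV
) -> VoltageSweep:
    """Subtract the liquid junction potential from the whole trace, once."""
    if sweep.junction_corrected:
        raise ValueError("sweep is already junction-corrected")
    return replace(
        sweep, voltage_mv=sweep.voltage_mv - correction_mv, junction_corrected=True
    )


def detect_aps(
    sweep: VoltageSweep,
    dvdt_threshold_v_per_s: float = DVDT_THRESHOLD_V_PER_S,
    peak_min_mv: float = -20.0,
    peak_prominence_mv: float = 20.0,
) -> list[APEvent]:
    """Detect APs and read each threshold off the phase plot.

    Suprathreshold excursions are located as voltage peaks (above
    ``peak_min_mv`` with ``peak_prominence_mv`` prominence); for each, the
    threshold is the voltage at the first sample of the contiguous
    upstroke run with dV/dt at or above the criterion.  Peaks without a
    criterion crossing are discarded.
    """
    if sweep.sample_rate_hz < 10_000:
        warnings.warn(
            f"sample rate {sweep.sample_rate_hz:g} Hz is below the 10 kHz "
            "recommended for phase-plot threshold detection",
            stacklevel=2,
        )
    v = sweep.voltage_mv
    if v.size < 3:
        return []
    dvdt = sweep.dvdt_v_per_s()
    peaks, _ = signal.find_peaks(v, height=peak_min_mv, prominence=peak_prominence_mv)
    events: list[APEvent] = []
    prev_bound = 0
    for p in peaks:
        # top of the upstroke: last suprathreshold-dV/dt sample before the peak
        j = int(p)
        while j > prev_bound and dvdt[j] < dvdt_threshold_v_per_s:
            j -= 1
        if dvdt[j] < dvdt_threshold_v_per_s:
            continue  # no phase-plot crossing: not an AP
        while j > prev_bound and dvdt[j - 1] >= dvdt_threshold_v_per_s:
            j -= 1
        events.append(
            APEvent(
                threshold_mv=float(v[j]),
                threshold_t_s=j / sweep.sample_rate_hz,
                peak_mv=float(v[p]),
                peak_t_s=p / sweep.sample_rate_hz,
                threshold_idx=j,
                peak_idx=int(p),
            )
        )
        prev_bound = int(p)
    # event end: the next event's threshold crossing, or end of sweep
    bounded: list[APEvent] = []
    for k, ev in enumerate(events):
        end = events[k + 1].threshold_idx if k + 1 < len(events) else v.size - 1
        bounded.append(replace(ev, end_idx=end))
    return bounded


def ap_kinetics(
    sweep: VoltageSweep, event: APEvent, window_ms: float = 10.0
) -> APEvent:
    """Complete an event with FWHM, AHP depth/latency and max slopes.

    The analysis window runs from the threshold crossing to the earlier of
    the next event's threshold crossing and ``window_ms`` after the peak.
    Events truncated by the sweep edge are completed as far as possible and
    flagged partial.
    """
    v = sweep.voltage_mv
    dt_ms = 1e3 / sweep.sample_rate_hz
    j, p = event.threshold_idx, event.peak_idx
    win_samples = int(round(window_ms / dt_ms))
    end = min(event.end_idx if event.end_idx > 0 else v.size - 1, p + win_samples)
    partial = end >= v.size - 1 or p >= v.size - 2

    amplitude = event.peak_mv - event.threshold_mv
    half = event.threshold_mv + amplitude / 2.0

    def _interp_cross(i0: int, i1: int, rising: bool) -> float:
        """Time (ms, sweep origin) where v crosses `half` between samples."""
        seg = v[i0 : i1 + 1]
        above = seg >= half
        idx = np.flatnonzero(above[:-1] != above[1:])
        if idx.size == 0:
            return float("nan")
        k = idx[0] if rising else idx[-1]
        v0, v1 = seg[k], seg[k + 1]
        frac = (half - v0) / (v1 - v0) if v1 != v0 else 0.0
        return (i0 + k + frac) * dt_ms

    t_up = _interp_cross(j, p, rising=True)
    t_down = _interp_cross(p, end, rising=False) if end > p else float("nan")
    fwhm = t_down - t_up if np.isfinite(t_up) and np.isfinite(t_down) else float("nan")
    if not np.isfinite(fwhm):
        partial = True

    if end > p:
        ahp_rel = int(np.argmin(v[p : end + 1]))
        ahp_idx = p + ahp_rel
        ahp_amplitude = event.threshold_mv - float(v[ahp_idx])
        time_to_ahp = (ahp_idx - j) * dt_ms
    else:
        ahp_amplitude = float("nan")
        time_to_ahp = float("nan")
        partial = True

    dvdt = sweep.dvdt_v_per_s()[j : end + 1]
    max_rise = float(dvdt.max()) if dvdt.size else float("nan")
    max_decay = float(dvdt.min()) if dvdt.size else float("nan")

    return replace(
        event,
        end_idx=end,
        fwhm_ms=float(fwhm),
        ahp_amplitude_mv=ahp_amplitude,
        time_to_ahp_ms=time_to_ahp,
        max_rise_slope_v_per_s=max_rise,
        max_decay_slope_v_per_s=max_decay,
        partial=partial,
    )


def evoked_rate(
    sweep: VoltageSweep, events: list[APEvent] | None = None
) -> EvokedResponse:
    """Evoked rate, latency to first spike, and first-10-spike ISI statistics.

    Rate = spikes (threshold crossings) inside the step window divided by
    the window duration.  The first-10 statistics use the first 10 evoked
    ISIs (all of them when fewer than 11 spikes fired).
    """
    if events is None:
        events = detect_aps(sweep)
    window = sweep.step_offset_s - sweep.step_onset_s
    t = np.array([ev.threshold_t_s for ev in events])
    in_step = t[(t >= sweep.step_onset_s) & (t < sweep.step_offset_s)]
    n = int(in_step.size)
    if n == 0:
        return EvokedResponse(rate_hz=0.0, n_spikes=0)
    latency = float(in_step[0] - sweep.step_onset_s)
    isis_ms = np.diff(in_step)[:10] * 1e3
    if isis_ms.size:
        mean_isi = float(isis_ms.mean())
        mean_if = float((1e3 / isis_ms).mean())
    else:
        mean_isi = float("nan")
        mean_if = float("nan")
    return EvokedResponse(
        rate_hz=n / window,
        n_spikes=n,
        latency_s=latency,
        mean_isi_first10_ms=mean_isi,
        mean_inst_freq_first10_hz=mean_if,
    )


def fi_auc(currents_pa: np.ndarray, rates_hz: np.ndarray) -> float:
    """Composite-trapezoid area under the F-I curve (Hz·pA)."""
    return float(np.trapezoid(np.asarray(rates_hz, float), np.asarray(currents_pa, float)))


def build_fi_curve(sweeps: list[VoltageSweep]) -> FICurve:
    """Assemble an F-I curve from a current-step family (sorted by current)."""
    ordered = sorted(sweeps, key=lambda s: s.current_step_pa)
    currents = np.array([s.current_step_pa for s in ordered])
    if np.unique(currents).size != currents.size:
        raise ValueError("duplicate current steps in the sweep family")
    rates = np.array([evoked_rate(s).rate_hz for s in ordered])
    return FICurve(currents_pa=currents, evoked_rate_hz=rates)


def passive_from_step(
    test_pulse: TestPulseRecording, dv_mv: float | None = None
) -> PassiveProperties:
    """Whole-cell passive properties from a voltage-clamp test pulse.

    Rs = ΔV / I_peak with the transient amplitude extrapolated to the step
    onset by a mono-exponential fit (so the finite sample rate does not
    clip the peak); Rin = ΔV / I_ss − Rs; τ from the fitted decay; Cm from
    τ = Cm · (Rs·Rin)/(Rs+Rin).  ΔV in mV and currents in pA put
    resistances naturally in GΩ; values are reported in MΩ, ms and pF.
    """
    dv = float(dv_mv if dv_mv is not None else test_pulse.dv_mv)
    sr = test_pulse.sample_rate_hz
    i_trace = np.asarray(test_pulse.current_pa, dtype=float)
    on = int(round(test_pulse.step_onset_s * sr))
    off = int(round(test_pulse.step_offset_s * sr))
    if not (0 < on < off <= i_trace.size):
        raise ValueError("test-pulse window must lie within the trace")
    baseline = float(i_trace[:on].mean())
    seg = i_trace[on:off] - baseline
    n_ss = max(1, (off - on) // 5)
    i_ss = float(seg[-n_ss:].mean())

    failed = False
    peak_idx = int(np.argmax(seg))
    t = (np.arange(seg.size) - peak_idx) / sr  # seconds past the sampled peak
    decay = seg[peak_idx:]
    t_decay = t[peak_idx:]
    a0 = max(float(decay[0] - i_ss), 1e-9)
    tau_s = float("nan")
    i_peak = float("nan")
    if decay.size >= 4 and a0 > abs(i_ss) * 0.01:
        # log-linear initial guess over the early decay
        pos = decay - i_ss
        k = np.flatnonzero(pos <= a0 * np.e**-2)
        k_end = int(k[0]) if k.size else decay.size
        k_end = max(k_end, 4)
        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                slope = np.polyfit(
                    t_decay[:k_end], np.log(np.clip(pos[:k_end], 1e-12, None)), 1
                )[0]
            tau0 = -1.0 / slope if slope < 0 else 1e-4
            popt, _ = optimize.curve_fit(
                lambda tt, a, tau: i_ss + a * np.exp(-tt / tau),
                t_decay,
                decay,
                p0=[a0, max(tau0, 1e-6)],
                maxfev=10_000,
            )
            amp, tau_s = float(popt[0]), float(popt[1])
            if amp <= 0 or tau_s <= 0:
                failed = True
            else:
                # extrapolate the transient back to the step onset
                t_onset = -peak_idx / sr
                i_peak = i_ss + amp * np.exp(-(t_onset) / tau_s)
        except (RuntimeError, ValueError):
            failed = True
    else:
        failed = True

    if failed or not np.isfinite(i_peak) or i_peak <= 0 or i_ss <= 0:
        return PassiveProperties(
            series_resistance_mohm=float("nan"),
            input_resistance_mohm=float("nan"),
            capacitance_pf=float("nan"),
            tau_ms=float("nan"),
            fit_failed=True,
        )

    rs_mohm = 1e3 * dv / i_peak  # mV/pA = GΩ → MΩ
    rin_mohm = 1e3 * dv / i_ss - rs_mohm
    tau_ms = tau_s * 1e3
    r_par = rs_mohm * rin_mohm / (rs_mohm + rin_mohm)
    cm_pf = 1e3 * tau_ms / r_par if r_par > 0 else float("nan")
    return PassiveProperties(
        series_resistance_mohm=rs_mohm,
        input_resistance_mohm=rin_mohm,
        capacitance_pf=cm_pf,
        tau_ms=tau_ms,
        fit_failed=False,
    )
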