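"""AP detection and kinetics, F-I curves, and passive-property QC."""

import dataclasses

import numpy as np
import pytest

from gnburst.excitability import (
    APEvent,
    FICurve,
    VoltageSweep,
    ap_kinetics,
    apply_junction_correction,
    build_fi_curve,
    detect_aps,
    evoked_rate,
    fi_auc,
    passive_from_step,
)
from gnburst.synthetic_data import (
    CellParams,
    generate_fi_family,
    generate_sweep,
    generate_test_pulse,
)


def flat_sweep(mv=-73.0, n=20000, sr=20000.0):
    return VoltageSweep(sr, np.full(n, mv), 0.0, 0.1, 0.9)


class TestJunctionCorrection:
    def test_constant_trace_shifts_by_13(self):
        sw = flat_sweep(-60.0)
        corrected = apply_junction_correction(sw)
        assert np.allclose(corrected.voltage_mv, -73.0)
        assert corrected.junction_corrected

    def test_zero_correction_is_identity(self):
        sw = flat_sweep(-60.0)
        out = apply_junction_correction(sw, correction_mv=0.0)
        np.testing.assert_array_equal(out.voltage_mv, sw.voltage_mv)

    def test_double_correction_rejected(self):
        corrected = apply_junction_correction(flat_sweep())
        with pytest.raises(ValueError, match="already"):
            apply_junction_correction(corrected)


class TestDetection:
    def test_flat_trace_has_no_events(self):
        assert detect_aps(flat_sweep()) == []

    def test_template_threshold_recovered_within_1mv(self, default_cell):
        for seed in range(10):
            sweep, truth = generate_sweep(default_cell, 60.0, seed=seed)
            events = detect_aps(sweep)
            assert len(events) == truth["n_spikes"]
            for ev in events:
                assert abs(ev.threshold_mv - truth["threshold_mv"]) < 1.0

    def test_two_close_spikes_give_two_ordered_events(self, default_cell):
        cell = dataclasses.replace(
            default_cell, gain_hz_per_pa=1.0, rheobase_pa=20.0, noise_sd_mv=0.0
        )
        sweep, truth = generate_sweep(cell, 40.0, seed=0)  # 20 Hz → 50-ms ISIs
        events = detect_aps(sweep)
        assert len(events) == truth["n_spikes"] >= 2
        times = [ev.peak_t_s for ev in events]
        assert times == sorted(times)
        assert len({ev.peak_idx for ev in events}) == len(events)

    def test_event_count_robust_to_small_noise(self, default_cell):
        quiet_cell = dataclasses.replace(default_cell, noise_sd_mv=0.0)
        sweep0, truth = generate_sweep(quiet_cell, 60.0, seed=0)
        n0 = len(detect_aps(sweep0))
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noisy = dataclasses.replace(
                sweep0, voltage_mv=sweep0.voltage_mv + rng.normal(0, 0.5, sweep0.voltage_mv.size)
            )
            assert len(detect_aps(noisy)) == n0 == truth["n_spikes"]

    def test_threshold_commutes_with_voltage_shift(self, default_cell):
        cell = dataclasses.replace(default_cell, noise_sd_mv=0.0)
        sweep, _ = generate_sweep(cell, 60.0, seed=0)
        shifted = dataclasses.replace(sweep, voltage_mv=sweep.voltage_mv - 13.0)
        t0 = [ev.threshold_mv for ev in detect_aps(sweep)]
        t1 = [ev.threshold_mv for ev in detect_aps(shifted)]
        np.testing.assert_allclose(np.array(t1), np.array(t0) - 13.0, atol=1e-9)

    def test_low_sample_rate_warns(self):
        sw = VoltageSweep(5000.0, np.full(5000, -73.0), 0.0, 0.1, 0.9)
        with pytest.warns(UserWarning, match="sample rate"):
            detect_aps(sw)


class TestKinetics:
    def test_symmetric_triangular_spike_fwhm_exactly_1ms(self):
        """Threshold −40, peak 0, 1-ms rise and 1-ms fall → FWHM = 1 ms."""
        sr = 100_000.0
        n_edge = int(1e-3 * sr)
        rise = np.linspace(-40.0, 0.0, n_edge + 1)
        fall = np.linspace(0.0, -40.0, n_edge + 1)[1:]
        pad = np.full(500, -40.0)
        v = np.concatenate([pad, rise, fall, pad])
        sw = VoltageSweep(sr, v, 10.0, 0.0, v.size / sr)
        ev = APEvent(
            threshold_mv=-40.0,
            threshold_t_s=500 / sr,
            peak_mv=0.0,
            peak_t_s=(500 + n_edge) / sr,
            threshold_idx=500,
            peak_idx=500 + n_edge,
            end_idx=500 + 2 * n_edge,
        )
        out = ap_kinetics(sw, ev)
        assert out.fwhm_ms == pytest.approx(1.0, abs=1e-9)

    def test_template_kinetics_match_closed_form(self, default_cell):
        cell = dataclasses.replace(default_cell, noise_sd_mv=0.0)
        sweep, truth = generate_sweep(cell, 60.0, seed=0)
        ev = ap_kinetics(sweep, detect_aps(sweep)[0])
        dt_ms = 1e3 / cell.sample_rate_hz
        # closed-form half-width of the quarter-sine rise / half-cosine fall
        amp = cell.peak_mv - cell.threshold_mv
        half = cell.threshold_mv + amp / 2
        t_up = (2 * cell.t_rise_ms / np.pi) * np.arcsin(0.5)
        ahp = cell.threshold_mv - cell.ahp_depth_mv
        frac = (half - ahp) / (cell.peak_mv - ahp)
        t_down = cell.t_rise_ms + cell.t_fall_ms * np.arccos(2 * frac - 1) / np.pi
        assert ev.fwhm_ms == pytest.approx(t_down - t_up, abs=2 * dt_ms)
        assert ev.ahp_amplitude_mv == pytest.approx(cell.ahp_depth_mv, abs=1.0)
        assert ev.time_to_ahp_ms == pytest.approx(
            cell.t_rise_ms + cell.t_fall_ms, abs=2 * dt_ms
        )
        assert ev.max_rise_slope_v_per_s > 0 > ev.max_decay_slope_v_per_s

    def test_event_at_sweep_edge_flagged_partial(self):
        sr = 20000.0
        v = np.full(1000, -73.0)
        v[-40:] = np.linspace(-73, 10, 40)  # upstroke truncated at the edge
        sw = VoltageSweep(sr, v, 10.0, 0.0, v.size / sr)
        ev = APEvent(
            threshold_mv=-44.0,
            threshold_t_s=(v.size - 25) / sr,
            peak_mv=10.0,
            peak_t_s=(v.size - 1) / sr,
            threshold_idx=v.size - 25,
            peak_idx=v.size - 1,
            end_idx=v.size - 1,
        )
        out = ap_kinetics(sw, ev)
        assert out.partial


class TestEvokedRate:
    def test_ten_spikes_in_one_second_step(self, default_cell):
        cell = dataclasses.replace(default_cell, noise_sd_mv=0.0)
        sweep, truth = generate_sweep(cell, 40.0, seed=0)  # 0.5·20 = 10 Hz
        resp = evoked_rate(sweep)
        assert resp.rate_hz == pytest.approx(10.0)
        assert resp.n_spikes == truth["n_spikes"] == 10

    def test_latency_matches_generator(self, default_cell):
        cell = dataclasses.replace(default_cell, latency_s=0.48, noise_sd_mv=0.0)
        sweep, _ = generate_sweep(cell, 60.0, seed=0)
        resp = evoked_rate(sweep)
        assert resp.latency_s == pytest.approx(0.48, abs=2e-3)

    def test_zero_spikes_flags_latency_undefined(self, default_cell):
        sweep, _ = generate_sweep(default_cell, 10.0, seed=0)  # below rheobase
        resp = evoked_rate(sweep)
        assert resp.rate_hz == 0.0
        assert np.isnan(resp.latency_s)

    def test_uniform_9ms_isis_give_111hz_instantaneous(self, default_cell):
        """A fast-firing cell with ~9-ms evoked ISIs: mean ISI 9 ms and mean
        instantaneous frequency near 111 Hz."""
        cell = dataclasses.replace(
            default_cell,
            gain_hz_per_pa=1.2,
            rheobase_pa=20.0,
            latency_s=0.01,
            noise_sd_mv=0.0,
        )
        sweep, truth = generate_sweep(cell, 112.6, seed=0)  # ≈111.1 Hz → 9-ms ISI
        resp = evoked_rate(sweep)
        assert resp.mean_isi_first10_ms == pytest.approx(9.0, rel=0.01)
        assert resp.mean_inst_freq_first10_hz == pytest.approx(111.1, rel=0.01)


class TestFICurve:
    def test_hand_computed_auc(self):
        assert fi_auc([0, 10, 20], [0, 10, 20]) == pytest.approx(200.0)

    def test_all_zero_rates_zero_auc(self):
        assert fi_auc([0, 10, 20], [0, 0, 0]) == 0.0

    def test_auc_matches_fine_grid_quadrature(self, rng):
        currents = np.arange(0.0, 101.0, 10.0)
        rates = np.sort(rng.uniform(0, 40, currents.size))
        auc = fi_auc(currents, rates)
        fine = np.linspace(0, 100, 100_001)
        riemann = np.interp(fine, currents, rates).sum() * (fine[1] - fine[0])
        assert auc == pytest.approx(riemann, rel=1e-3)

    def test_auc_linear_and_additive(self, rng):
        currents = np.arange(0.0, 51.0, 10.0)
        r1, r2 = rng.uniform(0, 30, 6), rng.uniform(0, 30, 6)
        assert fi_auc(currents, 2 * r1 + 3 * r2) == pytest.approx(
            2 * fi_auc(currents, r1) + 3 * fi_auc(currents, r2)
        )
        mid = 3
        total = fi_auc(currents, r1)
        assert total == pytest.approx(
            fi_auc(currents[: mid + 1], r1[: mid + 1]) + fi_auc(currents[mid:], r1[mid:])
        )

    def test_duplicate_currents_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            FICurve(np.array([0.0, 10.0, 10.0]), np.array([0.0, 1.0, 2.0]))

    def test_family_auc_matches_linear_gain_closed_form(self, default_cell):
        sweeps, truth = generate_fi_family(default_cell, seed=1)
        fi = build_fi_curve(sweeps)
        # trapezoid on a piecewise-linear-with-kink curve differs from the
        # continuous closed form only in the kink interval
        assert fi.auc == pytest.approx(truth["analytic_auc_hz_pa"], rel=0.05)


class TestPassive:
    def test_ideal_rc_cell_recovered_within_5pct(self, default_cell):
        rec, truth = generate_test_pulse(default_cell, seed=0)
        pp = passive_from_step(rec)
        assert pp.series_resistance_mohm == pytest.approx(truth["rs_mohm"], rel=0.05)
        assert pp.input_resistance_mohm == pytest.approx(truth["rin_mohm"], rel=0.05)
        assert pp.capacitance_pf == pytest.approx(truth["cm_pf"], rel=0.05)
        assert pp.qc_pass

    def test_high_series_resistance_fails_qc(self, default_cell):
        cell = dataclasses.replace(default_cell, rs_mohm=25.0)
        pp = passive_from_step(generate_test_pulse(cell, seed=1)[0])
        assert pp.series_resistance_mohm > 20.0
        assert not pp.qc_pass

    def test_low_input_resistance_fails_qc(self, default_cell):
        cell = dataclasses.replace(default_cell, rin_mohm=400.0)
        pp = passive_from_step(generate_test_pulse(cell, seed=2)[0])
        assert pp.input_resistance_mohm < 500.0
        assert not pp.qc_pass

    def test_non_decaying_transient_flags_failure(self):
        from gnburst.excitability import TestPulseRecording

        sr = 100_000.0
        n = int(0.015 * sr)
        current = np.zeros(n)
        on, off = int(0.002 * sr), int(0.012 * sr)
        current[on:off] = np.linspace(0, 100, off - on)  # rising, not decaying
        rec = TestPulseRecording(sr, current, 0.002, 0.012)
        pp = passive_from_step(rec)
        assert pp.fit_failed and not pp.qc_pass


class TestParameterRecoveryGrid:
    def test_group_means_rank_with_generator_settings(self, default_cell):
        """Across low/high threshold × low/high gain cells, recovered group
        means of threshold and F-I AUC preserve the generator ordering."""
        grids = {}
        currents = np.arange(0.0, 101.0, 20.0)
        for thr in (-48.0, -40.0):
            for gain in (0.3, 0.7):
                vals_thr, vals_auc = [], []
                for k in range(6):
                    cell = dataclasses.replace(
                        default_cell, threshold_mv=thr, gain_hz_per_pa=gain
                    )
                    sweeps, _ = generate_fi_family(cell, currents, seed=100 * k + 7)
                    fi = build_fi_curve(sweeps)
                    evs = detect_aps(sweeps[-1])
                    vals_thr.append(np.mean([e.threshold_mv for e in evs]))
                    vals_auc.append(fi.auc)
                grids[(thr, gain)] = (np.mean(vals_thr), np.mean(vals_auc))
        assert grids[(-48, 0.3)][0] < grids[(-40, 0.3)][0]
        assert grids[(-48, 0.7)][0] < grids[(-40, 0.7)][0]
        assert grids[(-48, 0.3)][1] < grids[(-48, 0.7)][1]
        assert grids[(-40, 0.3)][1] < grids[(-40, 0.7)][1]
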