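"""Peak metric measurement: accuracy, invariances, failure modes."""

import numpy as np
import pytest
from scipy.stats import exponnorm

from flowspps.exceptions import AnalysisError, PeakError
from flowspps.peak_analysis import (
    FLAG_LOW_SNR,
    FLAG_SLOW_COUPLING,
    analyze_run,
    correct_baseline,
    measure_peak,
)
from flowspps.synthetic_data import SimulationConfig, simulate_deprotection_trace
from flowspps.trace_io import CycleSchedule, CycleWindow, UVTrace

from conftest import gaussian_window

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def brute_force_fwhm(pdf, lo, hi, grid=0.001):
    """Independent half-height-crossing search on a fine fixed grid."""
    t = np.arange(lo, hi, grid)
    y = pdf(t)
    imax = int(np.argmax(y))
    half = y[imax] / 2.0
    left = np.flatnonzero(y[:imax] < half)[-1]
    tl = np.interp(half, [y[left], y[left + 1]], [t[left], t[left + 1]])
    right = imax + np.flatnonzero(y[imax:] < half)[0]
    tr = np.interp(half, [y[right], y[right - 1]], [t[right], t[right - 1]])
    return tr - tl


class TestMeasurePeak:
    def test_gaussian_analytic_height_and_fwhm(self):
        t, y = gaussian_window(sigma=2.0, height=1.0, dt=0.1)
        p = measure_peak(t, y)
        assert p.height_au == pytest.approx(1.000, abs=1e-3)
        assert p.fwhm_s == pytest.approx(GAUSS_FWHM_FACTOR * 2.0, abs=0.02)

    def test_emg_matches_fine_grid_oracle(self):
        sigma, tau = 2.0, 3.0
        t = np.arange(0.0, 90.0, 0.1)
        y = exponnorm.pdf(t, K=tau / sigma, loc=45.0, scale=sigma)
        p = measure_peak(t, y)
        oracle = brute_force_fwhm(
            lambda x: exponnorm.pdf(x, K=tau / sigma, loc=45.0, scale=sigma), 0, 90
        )
        assert oracle == pytest.approx(6.4724, abs=1e-3)  # frozen from the oracle
        assert p.fwhm_s == pytest.approx(oracle, rel=0.005)

    def test_fwhm_error_decreases_with_sampling_interval(self):
        errors = []
        for dt in (0.5, 0.1, 0.02):
            t, y = gaussian_window(sigma=2.0, dt=dt)
            p = measure_peak(t, y)
            errors.append(abs(p.fwhm_s - GAUSS_FWHM_FACTOR * 2.0))
        assert errors[0] > errors[1] > errors[2]
        assert errors[1] / (GAUSS_FWHM_FACTOR * 2.0) < 0.005

    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_absorbance_scaling_moves_h_and_area_only(self, c):
        t, y = gaussian_window()
        base, scaled = measure_peak(t, y), measure_peak(t, c * y)
        assert scaled.height_au == pytest.approx(c * base.height_au, rel=1e-9)
        assert scaled.area_au_s == pytest.approx(c * base.area_au_s, rel=1e-9)
        assert scaled.fwhm_s == pytest.approx(base.fwhm_s, rel=1e-9)

    @pytest.mark.parametrize("c", [0.5, 60.0])
    def test_time_scaling_moves_w_and_area_only(self, c):
        t, y = gaussian_window()
        base, scaled = measure_peak(t, y), measure_peak(c * t, y)
        assert scaled.fwhm_s == pytest.approx(c * base.fwhm_s, rel=1e-9)
        assert scaled.area_au_s == pytest.approx(c * base.area_au_s, rel=1e-9)
        assert scaled.height_au == pytest.approx(base.height_au, rel=1e-9)

    def test_all_zero_window_is_truncated_peak(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(PeakError, match="truncated peak"):
            measure_peak(t, np.zeros_like(t))

    def test_apex_on_edge_is_truncated_peak(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(PeakError, match="truncated peak"):
            measure_peak(t, np.exp(0.1 * t))  # monotone: apex at edge

    def test_unresolved_half_width(self):
        # peak far wider than the window: no half-height crossing
        t, y = gaussian_window(sigma=100.0, span=20.0, dt=0.1)
        with pytest.raises(PeakError, match="unresolved half-width"):
            measure_peak(t, y)

    def test_tiny_window_rejected(self):
        with pytest.raises(PeakError, match="fewer than"):
            measure_peak(np.arange(5.0), np.ones(5))

    def test_low_snr_flagged_but_returned(self):
        rng = np.random.default_rng(0)
        t, y = gaussian_window(sigma=2.0, height=0.05, dt=0.1)
        y = y + rng.normal(0.0, 0.02, len(t))
        p = measure_peak(t, y)
        assert FLAG_LOW_SNR in p.flags


class TestCorrectBaseline:
    def _schedule(self, n=1, span=90.0):
        return CycleSchedule(
            tuple(CycleWindow(f"A{i}", i, i * span, (i + 1) * span) for i in range(n))
        )

    def test_pure_linear_drift_removed(self):
        t = np.arange(0.0, 90.0, 0.1)
        trace = UVTrace(t, 0.05 + 0.002 * t)
        out = correct_baseline(trace, self._schedule())
        assert np.max(np.abs(out.absorbance_au)) < 1e-9

    def test_zero_trace_unchanged(self):
        t = np.arange(0.0, 90.0, 0.1)
        out = correct_baseline(UVTrace(t, np.zeros_like(t)), self._schedule())
        assert np.max(np.abs(out.absorbance_au)) < 1e-12

    def test_height_recovered_on_drift(self):
        t, y = gaussian_window(sigma=2.0, height=1.0, dt=0.1)
        drift = 0.3 + 0.004 * t
        corrected = correct_baseline(UVTrace(t, y + drift), self._schedule())
        p = measure_peak(corrected.time_s, corrected.absorbance_au)
        p0 = measure_peak(t, y)
        assert p.height_au == pytest.approx(p0.height_au, rel=0.005)

    def test_short_window_rejected(self):
        t = np.arange(0.0, 90.0, 0.1)
        sched = CycleSchedule((CycleWindow("A0", 0, 0.0, 1.0),))
        with pytest.raises(AnalysisError, match="shorter"):
            correct_baseline(UVTrace(t, np.zeros_like(t)), sched)


class TestAnalyzeRun:
    def test_clean_run_yields_one_peak_per_residue(self, clean_run):
        trace, schedule, _ = clean_run
        peaks, failures = analyze_run(trace, schedule)
        assert len(peaks) == len(schedule) and not failures
        assert all(not p.flags for p in peaks)
        for p, w in zip(peaks, schedule):
            assert w.start_s <= p.apex_time_s < w.end_s

    def test_exclusion_flags_but_still_measures(self, clean_run):
        trace, schedule, _ = clean_run
        label = schedule.labels[5]
        peaks, _ = analyze_run(trace, schedule, exclusions=(label,))
        flagged = [p for p in peaks if FLAG_SLOW_COUPLING in p.flags]
        assert [p.residue_label for p in flagged] == [label]
        assert flagged[0].fwhm_s > 0

    def test_dropout_cycle_reported_not_fatal(self, labels16):
        config = SimulationConfig(
            sequence_labels=labels16, peak_model="gaussian", noise_sd_au=0.0, seed=0
        )
        trace, schedule, _ = simulate_deprotection_trace(config)
        # blank one cycle entirely
        y = trace.absorbance_au.copy()
        w = schedule.windows[4]
        y[(trace.time_s >= w.start_s) & (trace.time_s < w.end_s)] = 0.0
        peaks, failures = analyze_run(UVTrace(trace.time_s, y), schedule)
        assert len(peaks) == 15
        assert len(failures) == 1 and failures[0][0] == w.residue_label

    def test_mostly_failing_run_is_run_level_error(self, clean_run):
        trace, schedule, _ = clean_run
        y = np.zeros_like(trace.absorbance_au)
        with pytest.raises(AnalysisError, match="windows failed"):
            analyze_run(UVTrace(trace.time_s, y), schedule)

    def test_measured_metrics_match_generator_truth(self, aggregating_run):
        trace, schedule, truth = aggregating_run
        peaks, _ = analyze_run(trace, schedule)
        w = np.array([p.fwhm_s for p in peaks])
        h = np.array([p.height_au for p in peaks])
        np.testing.assert_allclose(w, truth.w_true_s, rtol=0.01)
        np.testing.assert_allclose(h, truth.h_true_au, rtol=0.01)
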