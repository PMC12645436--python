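"""Aggregation factor: definition, invariances, onset rule, comparisons."""

import numpy as np
import pytest

from flowspps.aggregation_factor import (
    SUPPRESSED,
    AggregationProfile,
    compare_profiles,
    compute_af,
    detect_onset,
    with_onset,
)
from flowspps.exceptions import AnalysisError
from flowspps.model import AggregationMonitor
from flowspps.peak_analysis import FLAG_LOW_SNR, FLAG_SLOW_COUPLING, analyze_run
from flowspps.synthetic_data import SimulationConfig, simulate_deprotection_trace
from flowspps.trace_io import UVTrace

from conftest import make_peak


def profile_from(af_values, excluded=(), labels=None):
    labels = labels or tuple(f"X{i}" for i in range(len(af_values)))
    return AggregationProfile(
        labels=labels,
        af=np.asarray(af_values, float),
        reference_label=labels[0],
        excluded_labels=frozenset(excluded),
    )


class TestComputeAF:
    def test_identical_peaks_give_zero(self):
        peaks = [make_peak(f"X{i}", i, h=0.8, w=5.0) for i in range(6)]
        prof = compute_af(peaks, "X0")
        np.testing.assert_allclose(prof.af, 0.0, atol=1e-15)

    def test_reference_af_is_exactly_zero(self):
        peaks = [make_peak(f"X{i}", i, h=0.5 + 0.1 * i, w=4 + i) for i in range(5)]
        prof = compute_af(peaks, "X2")
        assert prof.af[2] == 0.0

    def test_double_width_same_height_gives_one(self):
        peaks = [make_peak("R", 0, h=1.0, w=4.0), make_peak("X", 1, h=1.0, w=8.0)]
        assert compute_af(peaks, "R").af[1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_width_and_height(self):
        ref = make_peak("R", 0, h=1.0, w=4.0)
        af_w = [compute_af([ref, make_peak("X", 1, h=1.0, w=w)], "R").af[1]
                for w in (4.0, 5.0, 6.0)]
        assert af_w[0] < af_w[1] < af_w[2]
        af_h = [compute_af([ref, make_peak("X", 1, h=h, w=4.0)], "R").af[1]
                for h in (0.5, 1.0, 1.5)]
        assert af_h[0] > af_h[1] > af_h[2]

    def test_missing_reference_errors(self):
        with pytest.raises(AnalysisError, match="missing"):
            compute_af([make_peak("A", 0)], "Z")

    def test_low_snr_reference_rejected(self):
        peaks = [make_peak("A", 0, flags=frozenset({FLAG_LOW_SNR})), make_peak("B", 1)]
        with pytest.raises(AnalysisError, match="unreliable reference"):
            compute_af(peaks, "A")

    def test_slow_coupling_flag_becomes_exclusion(self):
        peaks = [
            make_peak("A", 0),
            make_peak("B", 1, flags=frozenset({FLAG_SLOW_COUPLING})),
        ]
        assert compute_af(peaks, "A").excluded_labels == {"B"}

    def test_ratio_convention_reference_is_one(self):
        peaks = [make_peak("A", 0, h=1.0, w=4.0), make_peak("B", 1, h=1.0, w=7.0)]
        prof = compute_af(peaks, "A", convention="ratio")
        assert prof.af[0] == pytest.approx(1.0)
        assert prof.af[1] == pytest.approx((7.0 - 1.0) / 3.0)

    def test_af_increases_after_generated_onset(self):
        labels = tuple(f"X{i}" for i in range(16))
        config = SimulationConfig(
            sequence_labels=labels, onset_index=7, broadening_rate=0.15,
            yield_per_residue=0.97, noise_sd_au=0.0, seed=0,
        )
        trace, schedule, _ = simulate_deprotection_trace(config)
        peaks, _ = analyze_run(trace, schedule)
        af = compute_af(peaks, "X0").af
        assert np.all(np.diff(af[7:]) > 0)
        assert np.max(np.abs(af[:7])) < 0.05

    def test_scale_invariance_of_full_profile(self):
        """Rescaling absorbance x10 and time x60 leaves AF untouched."""
        labels = tuple(f"X{i}" for i in range(16))
        config = SimulationConfig(
            sequence_labels=labels, onset_index=7, broadening_rate=0.15,
            yield_per_residue=0.97, noise_sd_au=0.0, seed=0,
        )
        trace, schedule, _ = simulate_deprotection_trace(config)
        af0 = AggregationMonitor(trace, schedule, "X0").fit().profile.af

        scaled = UVTrace(trace.time_s * 60.0, trace.absorbance_au * 10.0)
        from flowspps.trace_io import CycleSchedule, CycleWindow
        sched60 = CycleSchedule(tuple(
            CycleWindow(w.residue_label, w.cycle_index, w.start_s * 60.0, w.end_s * 60.0)
            for w in schedule
        ))
        af1 = AggregationMonitor(scaled, sched60, "X0").fit().profile.af
        np.testing.assert_allclose(af1, af0, atol=1e-9)


class TestDetectOnset:
    def test_flat_profile_has_no_onset(self):
        assert detect_onset(profile_from([0.0] * 10)) is None

    def test_first_persistent_crossing_wins(self):
        prof = profile_from([0, 0, 0, 0.05, 0.3, 0.5, 0.8, 1.1])
        assert detect_onset(prof) == "X4"  # the 0.3 entry

    def test_single_spike_rejected_by_persistence(self):
        prof = profile_from([0, 0, 0, 0.9, 0.0, 0.0, 0.0, 0.0])
        assert detect_onset(prof, m=2) is None

    def test_baseline_region_cannot_be_called(self):
        prof = profile_from([0.5] * 10)
        assert detect_onset(prof, baseline_n=3) == "X3"

    def test_excluded_residues_are_skipped(self):
        # spike sits on an excluded (slow-coupling) residue: no onset
        prof = profile_from([0, 0, 0, 0.9, 0.05, 0.9, 0.02, 0.0, 0.0],
                            excluded=("X3", "X5"))
        assert detect_onset(prof) is None

    @pytest.mark.parametrize("kwargs", [{"theta": 0.0}, {"theta": -1.0}, {"m": 0}])
    def test_parameter_validation(self, kwargs):
        with pytest.raises(AnalysisError):
            detect_onset(profile_from([0.0] * 10), **kwargs)

    def test_too_short_profile_errors(self):
        with pytest.raises(AnalysisError, match="too short"):
            detect_onset(profile_from([0.0] * 4), baseline_n=3, m=2)


class TestCompareProfiles:
    def test_profile_vs_itself_has_zero_delay(self):
        prof = with_onset(profile_from([0, 0, 0, 0.3, 0.6, 0.9]))
        comp = compare_profiles([prof, prof], names=["a", "b"])
        assert comp.delays == {"a": 0, "b": 0}

    def test_delay_counted_in_residues(self):
        labels = tuple(f"X{i}" for i in range(14))
        base = with_onset(profile_from(
            [0, 0, 0, 0, 0, 0, 0, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6], labels=labels))
        late = with_onset(profile_from(
            [0] * 11 + [0.4, 0.6, 0.8], labels=labels))
        comp = compare_profiles([base, late], names=["base", "tagged"])
        assert comp.onsets["base"] == "X7" and comp.onsets["tagged"] == "X11"
        assert comp.delays["tagged"] == 4

    def test_suppressed_when_variant_never_aggregates(self):
        labels = tuple(f"X{i}" for i in range(10))
        base = with_onset(profile_from([0, 0, 0, 0.4, 0.6, 0.8, 1, 1, 1, 1], labels=labels))
        flat = with_onset(profile_from([0.0] * 10, labels=labels))
        comp = compare_profiles([base, flat], names=["base", "tagged"])
        assert comp.delays["tagged"] == SUPPRESSED

    def test_tag_residues_ignored_via_label_alignment(self):
        common = tuple(f"X{i}" for i in range(8))
        tagged_labels = tuple(f"R9{i}" for i in range(6)) + common
        base = with_onset(profile_from([0, 0, 0, 0.4, 0.6, 0.9, 1.2, 1.5], labels=common))
        tagged = with_onset(profile_from([0.0] * 14, labels=tagged_labels))
        comp = compare_profiles([base, tagged], names=["base", "tagged"])
        assert list(comp.table["residue_label"]) == list(common)

    def test_no_common_labels_errors(self):
        a = profile_from([0.0] * 10)
        b = profile_from([0.0] * 10, labels=tuple(f"Y{i}" for i in range(10)))
        with pytest.raises(AnalysisError, match="common"):
            compare_profiles([a, b])


class TestOnsetRecoveryEndToEnd:
    """Seeded replicate check of the full simulate→measure→AF→onset path."""

    def test_onset_recovered_under_noise(self, labels16):
        hits = 0
        for seed in range(5):
            config = SimulationConfig(
                sequence_labels=labels16, onset_index=7, broadening_rate=0.15,
                yield_per_residue=0.97, noise_sd_au=0.05, seed=seed,
            )
            trace, schedule, truth = simulate_deprotection_trace(config)
            res = AggregationMonitor(trace, schedule, labels16[0]).fit()
            hits += res.onset_label == truth.onset_label
        assert hits >= 4

    def test_slow_coupling_artifact_not_called(self, labels16):
        config = SimulationConfig(
            sequence_labels=labels16, onset_index=None, slow_coupling_index=6,
            slow_coupling_width_factor=2.5, noise_sd_au=0.0, seed=1,
        )
        trace, schedule, truth = simulate_deprotection_trace(config)
        res = AggregationMonitor(
            trace, schedule, labels16[0], exclusions=(labels16[6],)
        ).fit()
        assert truth.slow_coupling_label == labels16[6]
        assert res.onset_label is None
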