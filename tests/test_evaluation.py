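"""Tests of event matching and the validation statistics."""

import math

import numpy as np
import pytest

from gaitevents.errors import (PairingError, UndefinedStatisticError)
from gaitevents.evaluation import (bland_altman, build_report, classify_r,
                                   default_tolerance, error_range, isv,
                                   match_events, match_times,
                                   pearson_agreement, rmse, stance_times)
from gaitevents.events import EventSeries
from gaitevents.grf import detect_grf_events
from gaitevents.synthetic import SyntheticConfig, generate_trial


class TestMatching:
    def test_identity_match(self):
        me = match_times([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.5)
        assert [e for _, _, e in me.pairs] == [0.0, 0.0, 0.0]
        assert me.unmatched_detected == 0 and me.unmatched_reference == 0

    def test_nearest_one_to_one(self):
        me = match_times([1.02], [1.00, 2.00], 0.5)
        assert me.pairs == [(1.02, 1.00, pytest.approx(0.02))]
        assert me.unmatched_reference == 1

    def test_outside_tolerance_unmatched(self):
        me = match_times([3.50], [1.00], 0.5)
        assert me.pairs == [] and me.unmatched_detected == 1
        assert me.unmatched_reference == 1

    def test_empty_reference_is_not_an_error(self):
        me = match_times([1.0, 2.0], [], 0.5)
        assert me.unmatched_detected == 2

    def test_greedy_prefers_smallest_absolute_error(self):
        me = match_times([1.00, 1.08], [1.05], 0.5)
        ref_used = [r for _, r, _ in me.pairs]
        assert ref_used == [1.05]
        assert me.pairs[0][0] == 1.08  # |1.08-1.05| < |1.00-1.05|

    def test_match_events_splits_types(self):
        det = EventSeries("x", "left", [1.0], [1.6])
        ref = EventSeries("grf", "left", [1.01], [1.59])
        hs, to = match_events(det, ref, 0.5)
        assert hs.event_type == "heel_strike" and to.event_type == "toe_off"
        assert hs.n_matched == to.n_matched == 1

    def test_default_tolerance_half_median_stride(self):
        ref = EventSeries("grf", "left", [0.0, 1.1, 2.2, 3.3], [])
        assert default_tolerance(ref) == pytest.approx(0.55)
        merged = EventSeries("grf", "unassigned", [0.0, 0.55, 1.1, 1.65], [])
        assert default_tolerance(merged) == pytest.approx(0.55)


class TestScalarStatistics:
    def test_rmse_worked_values(self):
        assert rmse([0.0, 0.0, 0.0]) == 0.0
        assert rmse([0.010, -0.010, 0.010, -0.010]) == pytest.approx(0.010, abs=1e-12)
        assert rmse([0.003, 0.004]) == pytest.approx(math.sqrt(12.5) * 1e-3, abs=1e-9)

    def test_rmse_at_least_absolute_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            e = rng.normal(rng.uniform(-1, 1), rng.uniform(0, 1),
                           rng.integers(1, 30))
            assert rmse(e) >= abs(e.mean()) - 1e-12

    def test_error_range_worked_values(self):
        assert error_range([0.005, 0.005]) == 0.0
        assert error_range([-0.020, 0.030]) == pytest.approx(0.050)
        assert error_range([0.007]) == 0.0

    def test_isv_worked_values(self):
        assert isv([0.8, 0.8, 0.8]) == pytest.approx(0.0, abs=1e-9)
        assert isv([0.7, 0.8, 0.9]) == pytest.approx(12.5, abs=1e-9)
        assert isv([1.0, 3.0]) == pytest.approx(100.0 * math.sqrt(2.0) / 2.0, abs=1e-9)

    def test_isv_scale_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0.5, 1.5, 40)
        for c in (0.3, 2.0, 117.0):
            assert isv(c * v) == pytest.approx(isv(v), rel=1e-12)

    def test_undefined_statistics_raise(self):
        with pytest.raises(UndefinedStatisticError):
            rmse([])
        with pytest.raises(UndefinedStatisticError):
            error_range([])
        with pytest.raises(UndefinedStatisticError):
            isv([0.5])
        with pytest.raises(UndefinedStatisticError):
            isv([-1.0, 1.0])

    def test_bland_altman_worked_values(self):
        out = bland_altman([0.0, 0.0, 0.0], [0.01, 0.02, 0.03])
        assert out["mean_diff"] == pytest.approx(0.02, abs=1e-12)
        assert out["loa_low"] == pytest.approx(0.0004, abs=1e-9)
        assert out["loa_high"] == pytest.approx(0.0396, abs=1e-9)

    def test_bland_altman_degenerate_cases(self):
        same = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert same == {"mean_diff": 0.0, "loa_low": 0.0, "loa_high": 0.0}
        off = bland_altman([1.0, 2.0, 3.0], [1.05, 2.05, 3.05])
        assert off["loa_low"] == pytest.approx(0.05) == off["loa_high"]
        with pytest.raises(PairingError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_pearson_classification_bands(self):
        assert classify_r(1.0) == "high"
        assert classify_r(0.5) == "moderate"
        assert classify_r(0.35) == "unclassified-gap"
        assert classify_r(0.2) == "low"
        assert classify_r(-1.0) == "low"
        x = [1.0, 2.0, 3.0, 4.0]
        r, cls = pearson_agreement(x, x)
        assert r == pytest.approx(1.0) and cls == "high"
        r, cls = pearson_agreement(x, [-v for v in x])
        assert r == pytest.approx(-1.0) and cls == "low"
        with pytest.raises(UndefinedStatisticError):
            pearson_agreement(x, [1.0, 1.0, 1.0, 1.0])

    def test_oracle_equivalence_on_random_vectors(self):
        """rmse / range / ISV / Bland-Altman agree with plain-Python
        brute-force recomputation to 1e-12 on random inputs."""
        rng = np.random.default_rng(0)
        for _ in range(250):
            n = int(rng.integers(2, 40))
            e = rng.normal(0, 0.05, n)
            assert abs(rmse(e) - math.sqrt(sum(x * x for x in e) / n)) < 1e-12
            assert abs(error_range(e) - (max(e) - min(e))) < 1e-12
            v = rng.uniform(0.2, 1.8, n)
            mean = sum(v) / n
            sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))
            assert abs(isv(v) - sd / mean * 100.0) < 1e-12
            if n >= 3:
                a, b = rng.normal(0, 1, (2, n))
                d = [y - x for x, y in zip(a, b)]
                md = sum(d) / n
                sdd = math.sqrt(sum((x - md) ** 2 for x in d) / (n - 1))
                out = bland_altman(a, b)
                assert abs(out["mean_diff"] - md) < 1e-12
                assert abs(out["loa_high"] - (md + 1.96 * sdd)) < 1e-12
                assert abs(out["loa_low"] - (md - 1.96 * sdd)) < 1e-12


class TestStanceTimes:
    def test_basic_pairing(self):
        ev = EventSeries("grf", "left", [1.0, 2.1], [1.7, 2.8])
        rec = stance_times(ev)
        assert rec.stance_times == pytest.approx([0.7, 0.7])

    def test_unpaired_heel_strike_dropped(self):
        assert stance_times(EventSeries("grf", "left", [1.0], [])).stance_times == []
        rec = stance_times(EventSeries("grf", "left", [1.0, 2.1], [1.7]))
        assert rec.stance_times == pytest.approx([0.7])

    def test_literal_swing_reading(self):
        ev = EventSeries("grf", "left", [1.0, 2.1], [1.7, 2.8])
        rec = stance_times(ev, literal_swing=True)
        assert rec.stance_times == pytest.approx([0.4])  # TO 1.7 -> HS 2.1

    def test_implausible_durations_dropped(self):
        ev = EventSeries("grf", "left", [1.0], [5.0])
        rec = stance_times(ev, max_stance=2.0)
        assert rec.stance_times == [] and rec.n_dropped == 1

    def test_side_agnostic_series_skips_contralateral_toe_off(self):
        # merged feet: HS_R 0, TO_L 0.13, HS_L 0.55, TO_R 0.68, ...
        hs = [0.0, 0.55, 1.10, 1.65]
        to = [0.13, 0.68, 1.23, 1.78]
        rec = stance_times(EventSeries("imu", "unassigned", hs, to))
        assert rec.stance_times == pytest.approx([0.68, 0.68, 0.68])


@pytest.fixture(scope="module")
def clean_trial():
    cfg = SyntheticConfig(trial_duration=20.0, stride_period_cv=0.0,
                          noise_sd_grf=0.0, noise_sd_marker=0.0,
                          noise_sd_acc=0.0)
    return generate_trial(cfg)


class TestBuildReport:
    def _grf_detections(self, trial):
        return {"grf": [detect_grf_events(trial.vgrf_left, foot="left"),
                        detect_grf_events(trial.vgrf_right, foot="right")]}

    def test_zero_noise_grf_vs_truth(self, clean_trial):
        trial, truth = clean_trial
        refs = {"left": truth.series("left"), "right": truth.series("right")}
        report = build_report([self._grf_detections(trial)], [refs],
                              reference_name="truth")
        s = report.methods["grf"]
        assert s.hs_rmse <= 0.002 and s.to_rmse <= 0.002
        assert s.stance_isv < 0.5
        assert s.n_unmatched_reference == 0

    def test_empty_method_list(self, clean_trial):
        trial, truth = clean_trial
        refs = {"left": truth.series("left"), "right": truth.series("right")}
        report = build_report([{}], [refs])
        assert report.methods == {}

    def test_duplicated_participant_has_zero_cross_subject_sd(self, clean_trial):
        trial, truth = clean_trial
        refs = {"left": truth.series("left"), "right": truth.series("right")}
        det = self._grf_detections(trial)
        report = build_report([det, det], [refs, refs], reference_name="truth")
        s = report.methods["grf"]
        assert s.hs_rmse_sd == pytest.approx(0.0, abs=1e-15)

    def test_matched_pairs_table_consistent_with_summary(self, clean_trial):
        trial, truth = clean_trial
        refs = {"left": truth.series("left"), "right": truth.series("right")}
        report = build_report([self._grf_detections(trial)], [refs],
                              reference_name="truth")
        df = report.matched_pairs
        hs = df[df.event_type == "heel_strike"]
        assert len(hs) == report.methods["grf"].n_matched_hs
        # summary RMSE recomputable from the flat table
        assert report.methods["grf"].hs_rmse == pytest.approx(
            rmse(hs.error_s.to_numpy()), abs=1e-12)
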