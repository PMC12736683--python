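"""Tests of the two marker-based detectors."""

import numpy as np
import pytest

from gaitevents.errors import AlignmentError, DegenerateThresholdError
from gaitevents.omc import (MarkerTrack, Omc2Params, omc1_detect,
                            omc2_cycle_anchors, omc2_detect,
                            omc2_sagittal_speed, preprocess_track)
from gaitevents.peaks import qualified_minima
from gaitevents.signal_prep import UniformSignal
from conftest import nearest_errors

FS = 1000.0


def track(vert, ap=None, fs=FS, t0=0.0, marker="calcaneus", foot="left"):
    vert = np.asarray(vert, dtype=float)
    ap = np.zeros_like(vert) if ap is None else np.asarray(ap, dtype=float)
    return MarkerTrack(UniformSignal(vert, fs, t0), UniformSignal(ap, fs, t0),
                       marker, foot)


class TestOmc1:
    def test_cosine_marker_fixture(self):
        # position 0.05 cos(2 pi t): velocity minima at 0.25 + k,
        # maxima at 0.75 + k
        t = np.arange(int(3 * FS) + 1) / FS
        z = 0.05 * np.cos(2 * np.pi * t)
        ev = omc1_detect(track(z), track(z, marker="metatarsal_1"),
                         min_event_separation=0.5)
        assert nearest_errors(ev.heel_strikes, [0.25, 1.25, 2.25]).max() < 0.002
        assert nearest_errors(ev.toe_offs, [0.75, 1.75, 2.75]).max() < 0.002

    def test_constant_tracks_give_no_events(self):
        z = np.full(2000, 0.03)
        ev = omc1_detect(track(z), track(z, marker="metatarsal_1"))
        assert ev.n_events == 0

    def test_mismatched_rates_rejected(self):
        with pytest.raises(AlignmentError):
            omc1_detect(track(np.zeros(100), fs=1000.0),
                        track(np.zeros(100), fs=100.0, marker="metatarsal_1"))

    def test_zero_noise_trial_accuracy_and_consistency(self, zero_noise_trial,
                                                       run_config):
        """On a noise-free synthetic trial the foot-velocity events land
        within 10 ms of truth with near-constant error across cycles."""
        trial, truth = zero_noise_trial
        for cal, met, foot in ((trial.calcaneus_left, trial.metatarsal_left, "left"),
                               (trial.calcaneus_right, trial.metatarsal_right, "right")):
            ev = omc1_detect(preprocess_track(cal), preprocess_track(met))
            for det, ref in ((ev.heel_strikes, getattr(truth, f"heel_strikes_{foot}")),
                             (ev.toe_offs, getattr(truth, f"toe_offs_{foot}"))):
                err = nearest_errors(det, ref)
                assert np.abs(err).max() < 0.010
                assert err.std() < 0.002

    def test_time_shift_invariance(self):
        t = np.arange(int(3 * FS) + 1) / FS
        z = 0.05 * np.cos(2 * np.pi * t)
        ev0 = omc1_detect(track(z), track(z, marker="metatarsal_1"), 0.5)
        delta = 7.25
        ev1 = omc1_detect(track(z, t0=delta),
                          track(z, t0=delta, marker="metatarsal_1"), 0.5)
        np.testing.assert_allclose(np.array(ev1.heel_strikes),
                                   np.array(ev0.heel_strikes) + delta, atol=1e-12)
        np.testing.assert_allclose(np.array(ev1.toe_offs),
                                   np.array(ev0.toe_offs) + delta, atol=1e-12)

    def test_extrema_match_brute_force_oracle(self):
        """Qualified minima equal an exhaustive reimplementation of the
        documented rules (strict local minima, prominence floor, greedy
        descending-amplitude acceptance with separation)."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = np.cumsum(rng.standard_normal(500))
            floor, sep = 1.0, 25
            got = qualified_minima(x, floor, sep).tolist()
            assert got == _brute_force_minima(x, floor, sep)


def _brute_force_minima(x, prominence_floor, min_separation):
    y = -np.asarray(x, dtype=float)
    cand = [i for i in range(1, len(y) - 1) if y[i - 1] < y[i] > y[i + 1]]
    keep = []
    for i in cand:
        # prominence: height above the higher of the two bracketing valleys,
        # scanning outward to the nearest higher peak (or signal end)
        left = y[:i][::-1]
        right = y[i + 1:]
        lv = _valley_depth(left, y[i])
        rv = _valley_depth(right, y[i])
        if y[i] - max(lv, rv) >= prominence_floor:
            keep.append(i)
    accepted = []
    for i in sorted(keep, key=lambda j: (-y[j], j)):
        if all(abs(i - a) >= min_separation for a in accepted):
            accepted.append(i)
    return sorted(accepted)


def _valley_depth(segment, peak_height):
    lowest = peak_height
    for v in segment:
        if v > peak_height:
            break
        lowest = min(lowest, v)
    return lowest


class TestSagittalSpeed:
    def test_pythagorean_combination(self):
        t = np.arange(1000) / FS
        tr = track(3.0 * t, 4.0 * t)  # velocities 3 and 4 m/s
        speed = omc2_sagittal_speed(tr)
        np.testing.assert_allclose(speed.samples[1:-1], 5.0, atol=1e-9)

    def test_stationary_marker_zero_speed(self):
        tr = track(np.full(500, 0.02), np.full(500, 1.0))
        np.testing.assert_array_equal(omc2_sagittal_speed(tr).samples,
                                      np.zeros(500))

    def test_pure_vertical_motion(self):
        t = np.arange(2000) / FS
        z = 0.05 * np.sin(2 * np.pi * t)
        tr = track(z)
        speed = omc2_sagittal_speed(tr)
        v = np.gradient(z) * FS
        np.testing.assert_allclose(speed.samples, np.abs(v), atol=1e-12)


def _plateau_speed_tracks(rng, plateau_mean=0.002, plateau_sd=0.0005):
    """Piecewise heel-speed profile: 1 m/s swings dropping to a quiet
    plateau at integer seconds (positions are the cumulative integral, so
    the AP velocity is the desired speed)."""
    t = np.arange(int(6 * FS) + 1) / FS
    speed = np.full(t.size, 0.0)
    for k in range(6):
        swing = (t >= k + 0.6) & (t < k + 1.0)
        speed[swing] = 1.0 * np.sin(np.pi * (t[swing] - k - 0.6) / 0.4) ** 2 + 0.5
        quiet = (t >= k) & (t < k + 0.6)
        speed[quiet] = plateau_mean + plateau_sd * rng.standard_normal(quiet.sum())
    pos = np.concatenate([[0.0], np.cumsum(speed[:-1]) / FS])
    return track(np.zeros_like(pos), pos), speed, t


class TestOmc2:
    def test_quiet_window_defaults_follow_modified_protocol(self):
        p = Omc2Params()
        assert p.quiet_window_to == pytest.approx(0.075)
        assert p.quiet_window_hs == pytest.approx(0.050)

    def test_heel_strike_at_plateau_onset(self):
        rng = np.random.default_rng(3)
        heel, speed, t = _plateau_speed_tracks(rng)
        met_pos = np.cumsum(np.roll(speed, -300)) / FS  # lift shortly after anchor
        met = track(np.zeros_like(met_pos), met_pos, marker="metatarsal_1")
        anchors = np.arange(6) + 0.3
        ev = omc2_detect(heel, met, Omc2Params(), cycle_anchors=anchors)
        # plateaus are reached at integer seconds; threshold ~ mean + SD
        for k in (2, 3, 4, 5):
            assert np.abs(np.array(ev.heel_strikes) - k).min() < 0.003

    def test_degenerate_threshold_on_perfectly_flat_stance(self):
        rng = np.random.default_rng(3)
        heel, speed, t = _plateau_speed_tracks(rng, plateau_mean=0.0,
                                               plateau_sd=0.0)
        met = track(np.zeros(t.size), np.zeros(t.size), marker="metatarsal_1")
        with pytest.raises(DegenerateThresholdError):
            omc2_detect(heel, met, Omc2Params(),
                        cycle_anchors=np.arange(6) + 0.3)

    def test_threshold_floor_rescues_flat_stance(self):
        rng = np.random.default_rng(3)
        heel, speed, t = _plateau_speed_tracks(rng, plateau_mean=0.0,
                                               plateau_sd=0.0)
        met_pos = np.cumsum(np.roll(speed, -300)) / FS
        met = track(np.zeros_like(met_pos), met_pos, marker="metatarsal_1")
        ev = omc2_detect(heel, met, Omc2Params(threshold_floor=0.05),
                         cycle_anchors=np.arange(6) + 0.3)
        assert len(ev.heel_strikes) >= 4

    def test_threshold_nondecreasing_in_window_noise(self):
        from gaitevents.omc import _window_threshold
        rng = np.random.default_rng(5)
        base = rng.standard_normal(75)
        thresholds = [
            _window_threshold(np.abs(0.002 + sd * base), 37, 37, Omc2Params())
            for sd in (0.0001, 0.0005, 0.002, 0.01)
        ]
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))

    def test_time_shift_invariance_on_synthetic(self, noisy_trial, run_config):
        trial, _ = noisy_trial
        cal = preprocess_track(trial.calcaneus_left, cutoff=10.0)
        met = preprocess_track(trial.metatarsal_left, cutoff=10.0)
        params = Omc2Params(threshold_floor=0.05)
        ev0 = omc2_detect(cal, met, params)
        delta = 3.5

        def shift(tr):
            return MarkerTrack(
                UniformSignal(tr.vertical.samples, tr.fs, tr.t0 + delta),
                UniformSignal(tr.anteroposterior.samples, tr.fs, tr.t0 + delta),
                tr.marker, tr.foot)

        ev1 = omc2_detect(shift(cal), shift(met), params)
        np.testing.assert_allclose(np.array(ev1.heel_strikes),
                                   np.array(ev0.heel_strikes) + delta, atol=1e-9)
        np.testing.assert_allclose(np.array(ev1.toe_offs),
                                   np.array(ev0.toe_offs) + delta, atol=1e-9)

    def test_cycle_anchors_bracket_each_swing(self, noisy_trial):
        trial, truth = noisy_trial
        cal = preprocess_track(trial.calcaneus_left, cutoff=10.0)
        anchors = omc2_cycle_anchors(omc2_sagittal_speed(cal))
        # one anchor between consecutive heel strikes (mid-stance)
        hs = truth.heel_strikes_left
        for a, b in zip(hs[:-1], hs[1:]):
            assert ((anchors > a) & (anchors < b)).sum() == 1
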