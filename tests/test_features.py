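"""Kinematics, ethogram, plane classification, stimulus response, correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import waterflea as wf
from waterflea.features import (
    ETHOGRAM_STATES,
    FeatureParams,
    classify_states,
    correlation_matrix,
    ethogram,
    feature_table,
    kinematics,
    natural_features,
    smooth_series,
    stimulus_features,
)
from waterflea.stimulus import default_schedule
from waterflea.tracking import Detection, SegmentationParams

from conftest import make_track


class TestSmoothSeries:
    def test_documented_edge_rule(self):
        np.testing.assert_allclose(smooth_series([1, 2, 3, 4]), [1.5, 2, 3, 3.5])

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_series(np.full(20, 7.0)), 7.0)

    def test_noise_variance_reduced(self, rng):
        x = rng.normal(size=5000)
        assert smooth_series(x).var() < x.var()

    def test_empty_series(self):
        assert smooth_series([]).size == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_series([1, 2, 3], window=4)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_output_bounded_by_input_range(self, xs):
        out = smooth_series(xs)
        assert out.size == len(xs)
        assert out.min() >= min(xs) - 1e-9 and out.max() <= max(xs) + 1e-9


class TestKinematics:
    def test_constant_velocity_speed(self, straight_track):
        """(3,4) px/frame at 25 fps, 10 px/mm -> 12.5 mm/s every step."""
        kin = kinematics(straight_track, FeatureParams())
        np.testing.assert_allclose(kin.speed_mm_s, 12.5)
        np.testing.assert_allclose(kin.angvel_rad_s, 0.0, atol=1e-9)

    def test_uniform_circular_motion_angular_velocity(self):
        """Angular velocity = 2*pi/T for a circle traversed in period T."""
        fps, T, R = 25.0, 4.0, 100.0
        n = int(T * fps) + 10
        theta = 2 * np.pi * np.arange(n) / (T * fps)
        pos = np.column_stack([200 + R * np.cos(theta), 200 + R * np.sin(theta)])
        kin = kinematics(make_track(pos), FeatureParams())
        np.testing.assert_allclose(kin.angvel_rad_s, 2 * np.pi / T, rtol=0.01)

    def test_upward_motion_positive_vertical_velocity(self):
        pos = np.column_stack([np.full(10, 50.0), 100.0 - 2.0 * np.arange(10)])  # y decreasing = up
        kin = kinematics(make_track(pos), FeatureParams())
        assert (kin.vert_vel_mm_s > 0).all()

    def test_short_track_rejected(self):
        tr = make_track([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="detections"):
            kinematics(tr, FeatureParams())


class TestClassifyPlane:
    @pytest.mark.parametrize("circ,expected", [(0.95, "transverse"), (0.50, "sagittal"), (0.75, "unclassified")])
    def test_published_thresholds(self, circ, expected):
        d = Detection(frame=0, x=0, y=0, area=100, perimeter=40, major=12, minor=6, circularity=circ)
        assert wf.classify_plane(d, SegmentationParams()) == expected


class TestEthogram:
    def test_zero_displacement_is_all_pause(self):
        pos = np.full((100, 2), 40.0) + np.array([[0.001, 0]]) * np.arange(100)[:, None]
        _, probs = ethogram(make_track(pos), FeatureParams())
        assert probs["Pause"] == pytest.approx(1.0)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_probabilities_partition_unity(self, rng):
        pos = np.cumsum(rng.normal(0, 3, size=(200, 2)), axis=0) + 500
        _, probs = ethogram(make_track(pos), FeatureParams())
        assert set(probs) == set(ETHOGRAM_STATES)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_alternating_run_pause_blocks(self):
        """50-frame fast-straight / 50-frame still blocks -> ~0.5/0.5."""
        blocks = []
        x = 0.0
        for k in range(4):
            if k % 2 == 0:
                seg = np.column_stack([x + 5.0 * np.arange(50), np.zeros(50)])
                x = seg[-1, 0] + 5.0
            else:
                seg = np.full((50, 2), 0.0)
                seg[:, 0] = x
            blocks.append(seg)
        pos = np.vstack(blocks)
        pos[:, 1] = 100.0
        _, probs = ethogram(make_track(pos, major=12.0), FeatureParams())
        assert probs["FwdRun"] == pytest.approx(0.5, abs=0.05)
        assert probs["Pause"] == pytest.approx(0.5, abs=0.05)

    def test_cascade_agrees_with_hand_rule(self, rng):
        """Frame-by-frame agreement with the cascade applied literally."""
        p = FeatureParams()
        speed = rng.uniform(0, 4, size=300)
        angvel = rng.uniform(-8, 8, size=300)
        got = classify_states(speed, angvel, p)
        for s, a, state in zip(speed, angvel, got):
            if s <= p.pause_speed_max:
                want = "Pause"
            elif abs(a) >= p.spin_angvel_min:
                want = "Spin"
            elif abs(a) >= p.turn_angvel_min:
                want = "Turn"
            elif s >= p.run_speed_min:
                want = "FwdRun"
            elif s <= p.slow_speed_max:
                want = "FwdSlow"
            else:
                want = "Fwd"
            assert state == want


class TestNaturalFeatures:
    def test_constant_velocity_track(self, straight_track):
        f = natural_features(straight_track, FeatureParams(arena_h_px=480))
        assert f["speed_sd_mm_s"] == pytest.approx(0.0, abs=1e-9)
        assert f["ngdr"] == pytest.approx(1.0)
        assert f["p_turn"] == 0.0
        assert f["path_len_mm"] == pytest.approx(11 * 0.5)

    def test_deterministic_on_duplicate(self, straight_track):
        np.testing.assert_equal(natural_features(straight_track), natural_features(straight_track))

    def test_all_21_features_present(self, straight_track):
        from waterflea.features import NATURAL_FEATURES

        f = natural_features(straight_track, FeatureParams(arena_h_px=480))
        assert len(NATURAL_FEATURES) == 21
        assert set(f) == set(NATURAL_FEATURES)

    def test_cohort_mean_speed_recovers_configured(self):
        # straight swimmers: position smoothing is then unbiased for mean speed
        cfg = wf.CohortConfig(n_animals=40, duration_s=30.0, seed=31, heading_sd=0.0,
                              arena_w_px=2000, arena_h_px=2000, speed_age_slope=0.0)
        tracks = wf.truth_to_tracks(wf.simulate_trajectories(cfg, age_days=0.0))
        table = feature_table(tracks, FeatureParams(arena_h_px=2000))
        m = table["speed_mean_mm_s"]
        sem = m.std(ddof=1) / np.sqrt(len(m))
        assert abs(m.mean() - cfg.baseline_speed) < 3 * sem

    def test_missing_plane_reported_as_nan(self):
        pos = np.column_stack([3.0 * np.arange(20), np.zeros(20)])
        tr = make_track(pos, circularity=0.75)  # never classified
        f = natural_features(tr, FeatureParams())
        assert math.isnan(f["transverse_area_px2"]) and math.isnan(f["sagittal_area_px2"])

    def test_rigid_motion_invariance(self, rng):
        """Speed features invariant to translation and x-mirror; vertical
        velocity flips sign under y-mirror."""
        pos = np.cumsum(rng.normal(0, 3, size=(100, 2)), axis=0) + 500
        p = FeatureParams()
        base = natural_features(make_track(pos), p)
        shifted = natural_features(make_track(pos + [37.0, -12.0]), p)
        mirrored_x = natural_features(make_track(np.column_stack([1000 - pos[:, 0], pos[:, 1]])), p)
        for key in ("speed_mean_mm_s", "speed_sd_mm_s", "angvel_mean_rad_s", "ngdr"):
            assert base[key] == pytest.approx(shifted[key], rel=1e-9)
            assert base[key] == pytest.approx(mirrored_x[key], rel=1e-9)
        kin = kinematics(make_track(pos), p)
        kin_flip = kinematics(make_track(np.column_stack([pos[:, 0], 1000 - pos[:, 1]])), p)
        np.testing.assert_allclose(kin.vert_vel_mm_s, -kin_flip.vert_vel_mm_s, atol=1e-9)

    def test_segment_stability_on_stationary_statistics(self):
        """Features on overlapping 30 s windows of a 60 s track agree within 3 SEM."""
        cfg = wf.CohortConfig(n_animals=1, duration_s=60.0, seed=13, speed_age_slope=0.0,
                              arena_w_px=3000, arena_h_px=3000)
        tr = wf.truth_to_tracks(wf.simulate_trajectories(cfg, age_days=0.0))[0]
        p = FeatureParams()
        means, sems = [], []
        for t0 in (0, 10, 20, 30):
            sub = make_track(tr.xy[t0 * 25:(t0 + 30) * 25], start_frame=0)
            kin = kinematics(sub, p)
            means.append(kin.speed_mm_s.mean())
            sems.append(kin.speed_mm_s.std(ddof=1) / np.sqrt(kin.speed_mm_s.size))
        for m, s in zip(means, sems):
            assert abs(m - np.mean(means)) < 3 * s


class TestStimulusFeatures:
    def _cohort(self, gain, cv, seed=41):
        sched = default_schedule(90.0)  # covers all three stimuli (vibration ends at 80 s)
        cfg = wf.CohortConfig(n_animals=10, duration_s=90.0, seed=seed, speed_cv=cv,
                              stimulus_response_gain=gain, speed_age_slope=0.0,
                              arena_w_px=5000, arena_h_px=5000, drift_strength=0.2)
        truth = wf.simulate_trajectories(cfg, age_days=0.0, schedule=sched)
        return wf.truth_to_tracks(truth), sched

    @pytest.mark.parametrize("gain", [1.0, 2.0])
    def test_noiseless_gain_recovered_exactly(self, gain):
        tracks, sched = self._cohort(gain, cv=0.0)
        for tr in tracks:
            f = stimulus_features(tr, sched, FeatureParams())
            for label in ("weak_light", "strong_light", "vibration"):
                assert f[f"{label}_resp_ratio"] == pytest.approx(gain, rel=1e-9)

    def test_noisy_gain_recovered_within_sem(self):
        tracks, sched = self._cohort(2.0, cv=0.3)
        ratios = [stimulus_features(tr, sched, FeatureParams())["strong_light_resp_ratio"] for tr in tracks]
        sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 2.0) < 3 * sem

    def test_light_window_vertical_velocity_positive(self):
        tracks, sched = self._cohort(2.0, cv=0.3)
        vv = [stimulus_features(tr, sched, FeatureParams())["strong_light_vert_vel_mm_s"] for tr in tracks]
        assert np.mean(vv) > 0

    def test_absent_window_reported_missing(self):
        tracks, _ = self._cohort(2.0, cv=0.0)
        short_sched = default_schedule(30.0)  # only the weak-light window fits
        f = stimulus_features(tracks[0], short_sched, FeatureParams())
        assert math.isnan(f["vibration_resp_ratio"])
        assert not math.isnan(f["weak_light_resp_ratio"])

    def test_twelve_fields(self):
        from waterflea.features import STIMULUS_FEATURES

        assert len(STIMULUS_FEATURES) == 12


class TestCorrelationMatrix:
    def test_duplicate_feature_correlates_to_one(self, rng):
        a = rng.normal(size=50)
        df = pd.DataFrame({"f1": a, "f2": a.copy(), "f3": rng.normal(size=50)})
        m = correlation_matrix(df, columns=["f1", "f2", "f3"])
        assert m.loc["f1", "f2"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        m = correlation_matrix(df, columns=list("abcd"))
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m.values), 1.0)

    def test_independent_features_weakly_correlated(self, rng):
        n = 400
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("xyz"))
        m = correlation_matrix(df, columns=list("xyz"))
        off = m.values[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 3 / np.sqrt(n)).all()

    def test_constant_column_missing_not_zero(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30)})
        m = correlation_matrix(df, columns=["a", "b"])
        assert math.isnan(m.loc["a", "b"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame({"a": [1.0]}))
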