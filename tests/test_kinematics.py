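import dataclasses

import numpy as np
import pandas as pd
import pytest

from safefall import kinematics as kin
from safefall.pose_io import KP_INDEX, TrackedSequence
from safefall.synthetic_falls import PROFILE_DEFAULTS, PROFILES, simulate_fall

from conftest import make_random_sequence, noiseless_fall


def _set_hips(seq, y=None, x=None):
    for k in (KP_INDEX["left_hip"], KP_INDEX["right_hip"]):
        if y is not None:
            seq.keypoints[:, k, 1] = y
        if x is not None:
            seq.keypoints[:, k, 0] = x
    seq.visibility[:, [KP_INDEX["left_hip"], KP_INDEX["right_hip"]]] = True
    return seq


class TestVerticalVelocity:
    def test_constant_hip_gives_zero(self):
        rng = np.random.default_rng(0)
        seq = _set_hips(make_random_sequence(rng, n_frames=10), y=300.0)
        vy = kin.vertical_velocity(seq)
        assert np.all(vy[1:] == 0.0) and np.isnan(vy[0])

    def test_linear_descent_two_px_per_frame_at_60fps(self):
        rng = np.random.default_rng(1)
        n = 20
        seq = _set_hips(make_random_sequence(rng, n_frames=n), y=100 + 2.0 * np.arange(n))
        vy = kin.vertical_velocity(seq)
        np.testing.assert_allclose(vy[1:], 120.0)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(2)
        for i in range(20):
            seq = make_random_sequence(rng, n_frames=30, subject_id=f"S{i}")
            seq.visibility[:] = True
            vy = kin.vertical_velocity(seq)
            li, ri = KP_INDEX["left_hip"], KP_INDEX["right_hip"]
            y = (seq.keypoints[:, li, 1] + seq.keypoints[:, ri, 1]) / 2.0
            oracle = [np.nan] + [
                (y[t] - y[t - 1]) * seq.fps for t in range(1, seq.n_frames)
            ]
            assert np.array_equal(vy, np.array(oracle), equal_nan=True)

    def test_too_few_frames_raises(self):
        rng = np.random.default_rng(3)
        seq = make_random_sequence(rng, n_frames=5)
        seq.visibility[:, [KP_INDEX["left_hip"], KP_INDEX["right_hip"]]] = False
        with pytest.raises(kin.InsufficientDataError):
            kin.vertical_velocity(seq)


class TestTrunkInclination:
    def _frame(self, hip, shoulder):
        rng = np.random.default_rng(4)
        seq = make_random_sequence(rng, n_frames=1)
        seq.visibility[:] = True
        for k, pos in (
            ("left_hip", hip), ("right_hip", hip),
            ("left_shoulder", shoulder), ("right_shoulder", shoulder),
        ):
            seq.keypoints[0, KP_INDEX[k], :2] = pos
        return seq.frames[0]

    def test_upright_is_zero_degrees(self):
        assert kin.trunk_inclination(self._frame((100, 300), (100, 200))) == pytest.approx(0.0)

    def test_horizontal_is_ninety_degrees(self):
        assert kin.trunk_inclination(self._frame((100, 300), (200, 300))) == pytest.approx(90.0)

    def test_diagonal_is_fortyfive_degrees(self):
        assert kin.trunk_inclination(self._frame((0, 0), (100, -100))) == pytest.approx(45.0)

    def test_coincident_landmarks_raise(self):
        with pytest.raises(kin.UndefinedAngleError):
            kin.trunk_inclination(self._frame((50, 50), (50, 50)))


class TestAspectRatio:
    def test_values(self):
        rng = np.random.default_rng(5)
        seq = make_random_sequence(rng, n_frames=2)
        seq.bbox[0] = [0, 0, 100, 100]
        seq.bbox[1] = [0, 0, 60, 180]
        assert kin.aspect_ratio(seq.frames[0]) == pytest.approx(1.0)
        assert kin.aspect_ratio(seq.frames[1]) == pytest.approx(1.0 / 3.0)

    def test_lying_pose_exceeds_one(self):
        seq = noiseless_fall("controlled")
        ar = seq.bbox[-1, 2] / seq.bbox[-1, 3]
        assert ar > 1.0


class TestSegmentation:
    def test_impact_window_is_pm_200ms(self):
        seq = noiseless_fall("controlled")
        seg = kin.segment_phases(seq)
        half = round(0.2 * seq.fps)
        assert half == 12
        assert seg.impact == (seg.peak_decel_frame - 12, seg.peak_decel_frame + 13)
        assert seg.impact[1] - seg.impact[0] == 25
        assert seg.pre_fall == (0, seg.impact[0])
        assert seg.post_fall == (seg.impact[1], seq.n_frames)

    @pytest.mark.parametrize("profile", PROFILES)
    def test_peak_recovered_within_two_frames(self, profile):
        for seed in range(5):
            seq = noiseless_fall(profile, seed=seed)
            seg = kin.segment_phases(seq)
            assert abs(seg.peak_decel_frame - seq.meta["impact_frame_truth"]) <= 2

    def test_no_motion_raises_no_fall(self):
        rng = np.random.default_rng(6)
        seq = _set_hips(make_random_sequence(rng, n_frames=40), y=500.0, x=300.0)
        with pytest.raises(kin.NoFallError):
            kin.segment_phases(seq)

    def test_constant_velocity_descent_peaks_near_onset(self):
        """Zero interior deceleration: the tie-break convention picks the
        earliest candidate, just after the smoothed onset ramp."""
        rng = np.random.default_rng(7)
        n, onset = 80, 20
        y = np.concatenate([np.full(onset, 300.0), 300 + 5.0 * np.arange(1, n - onset + 1)])
        seq = _set_hips(make_random_sequence(rng, n_frames=n), y=y, x=400.0)
        seg = kin.segment_phases(seq, smooth_window=5)
        assert onset - 2 <= seg.peak_decel_frame <= onset + 8


class TestMetrics:
    def test_static_sequence_all_motion_metrics_zero(self):
        rng = np.random.default_rng(8)
        seq = make_random_sequence(rng, n_frames=10)
        seq.visibility[:] = True
        seq.keypoints[:] = seq.keypoints[0]
        m = kin.extract_metrics(seq)
        assert m.avg_velocity == m.max_velocity == 0.0
        assert m.movement_range_x == m.movement_range_y == 0.0
        assert m.avg_descent_rate == m.high_movement_frames == 0.0
        assert m.avg_confidence == pytest.approx(seq.keypoints[:, :, 2].mean())

    def test_order_statistics_invariants(self, default_cohort):
        for seq in default_cohort[:40]:
            m = kin.extract_metrics(seq)
            assert m.max_velocity >= m.avg_velocity
            assert m.max_acceleration >= m.avg_acceleration
            assert m.max_descent_rate >= m.avg_descent_rate
            assert m.total_vertical_change <= m.movement_range_y + 1e-9
            assert 0.0 <= m.avg_confidence <= 1.0

    def test_translation_invariance(self):
        seq = noiseless_fall("controlled")
        moved = seq.copy()
        moved.keypoints[:, :, 0] += 111.0
        moved.bbox[:, 0] += 111.0
        a, b = kin.extract_metrics(seq).as_dict(), kin.extract_metrics(moved).as_dict()
        for name, val in a.items():
            assert b[name] == pytest.approx(val, rel=1e-9, abs=1e-9), name

    def test_mirror_invariance(self):
        seq = noiseless_fall("chaotic")
        w = seq.frame_size[0]
        mirrored = seq.copy()
        mirrored.keypoints[:, :, 0] = w - mirrored.keypoints[:, :, 0]
        mirrored.bbox[:, 0] = w - (mirrored.bbox[:, 0] + mirrored.bbox[:, 2])
        a = kin.extract_metrics(seq).as_dict()
        b = kin.extract_metrics(mirrored).as_dict()
        for name, val in a.items():
            assert b[name] == pytest.approx(val, rel=1e-9, abs=1e-9), name

    def test_velocities_scale_linearly_with_coordinates(self):
        seq = noiseless_fall("controlled")
        scaled = seq.copy()
        c = 0.5
        scaled.keypoints[:, :, :2] *= c
        scaled.bbox *= c
        a = kin.extract_metrics(seq)
        b = kin.extract_metrics(scaled)
        assert b.avg_velocity == pytest.approx(c * a.avg_velocity, rel=1e-9)
        assert b.max_descent_rate == pytest.approx(c * a.max_descent_rate, rel=1e-9)

    def test_category_tags(self):
        cats = pd.Series(kin.METRIC_CATEGORIES)
        assert (cats == "fall").sum() == 3
        assert (cats == "stability").sum() == 3
        assert (cats == "movement").sum() == 9
        assert len(kin.METRIC_NAMES) == 15


class TestFrameFeatures:
    def test_shape_matches_documented_schema(self):
        seq = noiseless_fall("controlled")
        df = kin.extract_frame_features(seq)
        assert len(df) == seq.n_frames
        assert list(df.columns) == ["frame_index"] + kin.frame_feature_columns()
        assert len(kin.frame_feature_columns()) == 150

    def test_constant_pose_has_zero_derivatives(self):
        rng = np.random.default_rng(9)
        seq = make_random_sequence(rng, n_frames=8)
        seq.visibility[:] = True
        seq.keypoints[:] = seq.keypoints[0]
        seq.bbox[:] = seq.bbox[0]
        df = kin.extract_frame_features(seq)
        d_cols = [c for c in df.columns if c.startswith(("d_", "dd_"))]
        vals = df[d_cols].to_numpy()[2:]  # first rows are NaN by contract
        assert np.nanmax(np.abs(vals)) == 0.0

    def test_derivatives_match_brute_force(self):
        rng = np.random.default_rng(10)
        seq = make_random_sequence(rng, n_frames=25)
        seq.visibility[:] = True
        df = kin.extract_frame_features(seq)
        fps = seq.fps
        for col in ("nose_x", "left_wrist_y", "mid_hip_y"):
            raw = df[col].to_numpy()
            d = df[f"d_{col}"].to_numpy()
            dd = df[f"dd_{col}"].to_numpy()
            d_oracle = np.array(
                [np.nan] + [(raw[t] - raw[t - 1]) * fps for t in range(1, len(raw))]
            )
            dd_oracle = np.array(
                [np.nan] + [(d_oracle[t] - d_oracle[t - 1]) * fps for t in range(1, len(raw))]
            )
            assert np.array_equal(d, d_oracle, equal_nan=True)
            assert np.array_equal(dd, dd_oracle, equal_nan=True)
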