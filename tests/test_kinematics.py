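import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speedkin.camera_motion import CameraTrajectory
from speedkin.core import REDUCED_NAMES, SkeletonFrame
from speedkin.kinematics import (KinematicsError, auto_cutoff, cog,
                                 frames_to_series, interpolate_missing,
                                 joint_angle, joint_angle_series, lowpass,
                                 trunk_inclination_series, velocity)


def make_series(positions, conf=None):
    """positions: (n, 2) applied to every keypoint; conf: (n,) or None."""
    n = len(positions)
    frames = []
    for i in range(n):
        c = 0.9 if conf is None else conf[i]
        kps = {name: (positions[i][0], positions[i][1], c)
               for name in REDUCED_NAMES}
        frames.append(SkeletonFrame(frame=i, keypoints=kps))
    return frames_to_series(frames, min_confidence=0.1)


class TestInterpolation:
    def test_linear_fill_of_interior_gap(self):
        ser = make_series([(0.0, 0.0), (5.0, 5.0), (2.0, 2.0)],
                          conf=[0.9, 0.0, 0.9])
        filled = interpolate_missing(ser)
        np.testing.assert_allclose(filled.xy["Nose"][1], (1.0, 1.0))
        assert filled.interpolated["Nose"][1]
        assert not filled.interpolated["Nose"][0]

    def test_no_gaps_is_identity(self):
        pts = [(float(i), float(2 * i)) for i in range(5)]
        ser = interpolate_missing(make_series(pts))
        np.testing.assert_allclose(ser.xy["Neck"], pts)
        assert not ser.interpolated["Neck"].any()

    def test_edge_gaps_take_nearest_valid(self):
        ser = make_series([(9.0, 9.0), (1.0, 1.0), (2.0, 2.0)],
                          conf=[0.0, 0.9, 0.9])
        filled = interpolate_missing(ser)
        np.testing.assert_allclose(filled.xy["Nose"][0], (1.0, 1.0))

    def test_under_two_valid_samples_left_missing(self):
        ser = make_series([(1.0, 1.0), (2.0, 2.0)], conf=[0.9, 0.0])
        filled = interpolate_missing(ser)
        assert np.isnan(filled.xy["Nose"][1]).all()

    def test_dropout_fill_on_trunk_keypoints_within_3_sigma(self, run_noisy):
        """5% dropout on slow trunk keypoints is bridged to within 3 sigma."""
        from speedkin.io_formats import select_athlete
        cfg = run_noisy.config
        sk = select_athlete(run_noisy.pose_frames, "left", cfg.image_w)
        for s in sk:
            s.keypoints = {k: (x, cfg.image_h - y if c > 0 else y, c)
                           for k, (x, y, c) in s.keypoints.items()}
        ser = interpolate_missing(frames_to_series(sk, 0.1))
        for name in ("Neck", "MidHip"):
            filled = ser.interpolated[name]
            assert filled.any()
            err = np.abs(ser.xy[name][filled]
                         - run_noisy.truth.keypoints_px[name][filled])
            assert err.max() <= 3 * cfg.sigma_px


class TestJointAngle:
    def test_right_angle(self):
        assert joint_angle((1, 0), (0, 0), (0, 1)) == pytest.approx(90.0)

    def test_collinear_cases(self):
        assert joint_angle((-1, 0), (0, 0), (1, 0)) == pytest.approx(180.0)
        assert joint_angle((2, 0), (0, 0), (1, 0)) == pytest.approx(0.0)

    def test_degenerate_returns_nan(self):
        assert np.isnan(joint_angle((0, 0), (0, 0), (1, 1)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-np.pi, np.pi), st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0.1, 10.0))
    def test_similarity_invariance(self, rot, tx, ty, scale):
        a, j, b = np.array([2.0, 0.3]), np.array([0.5, 0.5]), np.array([-1.0, 1.5])
        base = joint_angle(a, j, b)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        t = np.array([tx, ty])
        fa, fj, fb = (scale * R @ p + t for p in (a, j, b))
        assert joint_angle(fa, fj, fb) == pytest.approx(base, abs=1e-9)

    def test_angle_series_bounds_and_interp_mask(self, res_noisy):
        for name, ser in res_noisy.angles.items():
            assert np.all(ser.theta_deg >= -1e-9)
            assert np.all(ser.theta_deg <= 180.0 + 1e-9)


class TestCog:
    def test_degenerate_pose_collapses_to_point(self, table):
        pts = {n: (3.0, 7.0) for n in REDUCED_NAMES}
        np.testing.assert_allclose(cog(pts, table), (3.0, 7.0), atol=1e-12)

    def test_mirror_symmetry(self, table):
        rng = np.random.default_rng(0)
        pts = {}
        for n in REDUCED_NAMES:
            if n.startswith("R"):
                continue
            pts[n] = rng.uniform(-5, 5, 2)
        for n in REDUCED_NAMES:
            if n.startswith("R"):
                mirror = pts["L" + n[1:]]
                pts[n] = np.array([-mirror[0], mirror[1]])
        # midline keypoints on the axis
        for n in ("Nose", "Neck", "MidHip"):
            pts[n] = np.array([0.0, pts[n][1]])
        assert cog(pts, table)[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_per_segment_summation(self, table):
        rng = np.random.default_rng(7)
        pts = {n: rng.uniform(0, 100, 2) for n in REDUCED_NAMES}
        # independent oracle: explicit loop over the twelve segments
        expected = np.zeros(2)
        for seg in table.segments:
            p = np.asarray(pts[seg.proximal_kp])
            d = np.asarray(pts[seg.distal_kp])
            expected += seg.mass_frac * (p + seg.com_ratio * (d - p))
        np.testing.assert_allclose(cog(pts, table), expected, atol=1e-9)

    def test_inside_convex_hull_of_keypoints(self, table):
        rng = np.random.default_rng(3)
        pts = {n: rng.uniform(0, 10, 2) for n in REDUCED_NAMES}
        c = cog(pts, table)
        arr = np.array(list(pts.values()))
        assert arr[:, 0].min() - 1e-9 <= c[0] <= arr[:, 0].max() + 1e-9
        assert arr[:, 1].min() - 1e-9 <= c[1] <= arr[:, 1].max() + 1e-9

    def test_missing_endpoint_raises(self, table):
        pts = {n: (1.0, 1.0) for n in REDUCED_NAMES}
        pts["RWrist"] = (np.nan, np.nan)
        with pytest.raises(KinematicsError, match="forearm_r"):
            cog(pts, table)


class TestVelocity:
    def test_arithmetic_oracle(self):
        # dy = 10 px, gamma = 2 px, fps = 24, s = 400 px/m -> 0.72 m/s
        track = np.array([[0.0, 0.0], [0.0, 10.0]])
        g = CameraTrajectory(gamma_px=[2.0], n_inliers=[10])
        v = velocity(track, g, 400.0, fps=24.0)
        assert v[0, 1] == pytest.approx(0.72)
        assert v[0, 0] == 0.0

    def test_scaling_invariance(self):
        rng = np.random.default_rng(0)
        track = rng.uniform(0, 500, (20, 2))
        g = CameraTrajectory(gamma_px=rng.uniform(-5, 5, 19), n_inliers=[10] * 19)
        v1 = velocity(track, g, 400.0, fps=24.0)
        g2 = CameraTrajectory(gamma_px=3.0 * g.gamma_px, n_inliers=g.n_inliers)
        v2 = velocity(3.0 * track, g2, 1200.0, fps=24.0)
        np.testing.assert_allclose(v1, v2, atol=1e-9)

    def test_nonpositive_scale_rejected(self):
        track = np.zeros((3, 2))
        g = CameraTrajectory(gamma_px=[0.0, 0.0], n_inliers=[1, 1])
        with pytest.raises(KinematicsError):
            velocity(track, g, 0.0, fps=24.0)

    def test_static_climber_under_pan_is_exactly_zero(self, res_static):
        assert np.linalg.norm(res_static.cog.v_ms, axis=1).max() < 1e-6


class TestFiltering:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.3)
        np.testing.assert_allclose(lowpass(x, 3.0, 24.0), x, atol=1e-9)

    def test_high_frequency_attenuated_20db(self):
        fps, n = 240.0, 4800
        t = np.arange(n) / fps
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 10.0 * t)
        y = lowpass(x, 3.0, fps)
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(n, 1 / fps)
        amp_1 = spec[np.argmin(np.abs(freqs - 1.0))]
        amp_10 = spec[np.argmin(np.abs(freqs - 10.0))]
        assert amp_10 < amp_1 / 100.0  # >= 40 dB down, well past 20 dB

    def test_zero_phase_no_lag_on_step_midpoint(self):
        x = np.concatenate([np.zeros(100), np.ones(100)])
        y = lowpass(x, 3.0, 24.0)
        # crossing of 0.5 stays at the step location
        assert abs(int(np.argmax(y > 0.5)) - 100) <= 1

    def test_short_series_returned_unfiltered(self):
        x = np.arange(5, dtype=float)
        np.testing.assert_allclose(lowpass(x, 3.0, 24.0), x)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.zeros(100), 13.0, 24.0)

    def test_auto_cutoff_pure_sine(self):
        t = np.arange(0, 6, 1 / 24)
        c = auto_cutoff(np.sin(2 * np.pi * 1.0 * t), 24.0)
        assert 1.0 <= c <= 2.0


class TestTrunkInclination:
    def test_upright_trunk_is_zero_degrees(self):
        pts = [(0.0, 0.0)] * 3
        ser = make_series(pts)
        ser.xy["RShoulder"][:] = (110.0, 100.0)
        ser.xy["LShoulder"][:] = (90.0, 100.0)
        ser.xy["RHip"][:] = (105.0, 50.0)
        ser.xy["LHip"][:] = (95.0, 50.0)
        out = trunk_inclination_series(ser)
        np.testing.assert_allclose(out.theta_deg, 0.0, atol=1e-9)

    def test_45_degree_lean(self):
        ser = make_series([(0.0, 0.0)] * 2)
        ser.xy["RShoulder"][:] = (60.0, 60.0)
        ser.xy["LShoulder"][:] = (40.0, 40.0)
        ser.xy["RHip"][:] = (10.0, 10.0)
        ser.xy["LHip"][:] = (-10.0, -10.0)
        out = trunk_inclination_series(ser)
        np.testing.assert_allclose(out.theta_deg, 45.0, atol=1e-9)


class TestFullPipelineSpeedRecovery:
    def test_noiseless_cog_speed_profile_recovered(self, run_clean, res_clean):
        fps = run_clean.config.fps
        ts = np.linalg.norm(np.diff(run_clean.truth.cog_world, axis=0), axis=1) * fps
        assert np.abs(res_clean.cog_speed_filt - ts).max() < 0.05
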