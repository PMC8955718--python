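import numpy as np
import pytest

from speedkin.camera_motion import CameraTrajectory
from speedkin.core import load_route_map
from speedkin.io_formats import DetectionBox
from speedkin.scale_calibration import (CalibrationError, fit_scale_model,
                                        identify_holds, iterate_alpha,
                                        measure_scale_samples, pairwise_scale,
                                        track_and_identify_holds, track_holds)


def flat_gamma(values):
    return CameraTrajectory(gamma_px=np.asarray(values, dtype=float),
                            n_inliers=np.full(len(values), 50))


class TestPairwiseScale:
    def test_worked_example_400_px_per_m(self):
        # pixel offsets (300, 350.4) against map distances (0.75, 0.876) m
        s = pairwise_scale((0.0, 0.0), (300.0, 350.4), (0.0, 0.0), (0.75, 0.876))
        assert s == pytest.approx(400.0, abs=1e-9)

    def test_equal_ratios(self):
        assert pairwise_scale((0, 0), (100, 100), (0, 0), (1, 1)) == 100.0

    def test_single_axis_fallback_on_zero_map_distance(self):
        s = pairwise_scale((0, 0), (5, 200), (0, 0), (0.0, 0.5))
        assert s == pytest.approx(400.0)

    def test_zero_distance_both_axes_raises(self):
        with pytest.raises(CalibrationError):
            pairwise_scale((0, 0), (5, 5), (1, 1), (1, 1))


class TestIterateAlpha:
    def test_zero_shift_is_fixed_point(self):
        alpha = iterate_alpha(np.zeros(10), B=1000.0, alpha0=0.3)
        np.testing.assert_allclose(alpha, 0.3)

    def test_recurrence_oracle_values(self):
        # alpha_{i+1} = (10/1000) cos(alpha_i) + alpha_i from alpha_0 = 0
        alpha = iterate_alpha(np.full(3, 10.0), B=1000.0, alpha0=0.0)
        np.testing.assert_allclose(
            alpha, [0.0, 0.01, 0.019999500, 0.029997500], atol=1e-9)

    def test_matches_generator_recurrence_exactly(self, run_clean, res_clean):
        tr = run_clean.truth
        alpha = iterate_alpha(res_clean.gamma.gamma_px, tr.params["B"],
                              tr.params["alpha0"])
        assert np.abs(alpha - tr.camera_alpha).max() < 1e-9

    def test_zero_gain_rejected(self):
        with pytest.raises(ValueError):
            iterate_alpha(np.ones(3), B=0.0, alpha0=0.0)


class TestHoldTracking:
    def _boxes(self, centers_by_frame, kind="hand"):
        return [DetectionBox(f, kind, x, y, 40.0, 40.0, 0.9)
                for f, pts in centers_by_frame.items() for x, y in pts]

    def test_static_scene_one_track_per_hold(self):
        dets = self._boxes({f: [(100.0, 200.0), (110.0, 500.0)] for f in range(5)})
        tracks = track_holds(dets, flat_gamma(np.zeros(4)))
        assert len(tracks) == 2
        assert all(len(t.frames) == 5 for t in tracks)

    def test_compensation_invariance_under_constant_pan(self):
        # same wall, camera panning 30 px/frame: boxes drift down in the image
        static = {f: [(100.0, 200.0), (110.0, 500.0)] for f in range(5)}
        panned = {f: [(100.0, 200.0 - 30.0 * f), (110.0, 500.0 - 30.0 * f)]
                  for f in range(5)}
        t_static = track_holds(self._boxes(static), flat_gamma(np.zeros(4)))
        t_panned = track_holds(self._boxes(panned), flat_gamma(np.full(4, 30.0)))
        assert len(t_panned) == len(t_static) == 2
        for a, b in zip(t_static, t_panned):
            np.testing.assert_allclose(a.mean_comp(), b.mean_comp(), atol=1e-9)

    def test_single_track_is_insufficient_for_calibration(self):
        dets = self._boxes({f: [(100.0, 200.0)] for f in range(5)})
        tracks = track_holds(dets, flat_gamma(np.zeros(4)))
        with pytest.raises(CalibrationError, match="insufficient"):
            identify_holds(tracks, load_route_map())

    def test_identification_matches_truth_on_clean_run(self, run_clean, res_clean):
        # truth hold positions and track centres are both y-up
        tr = run_clean.truth
        checked = 0
        for t in res_clean.tracks:
            if t.map_id is None:
                continue
            f = t.first_seen
            cx, cy = t.centers_px[0]
            nearest = min(tr.holds_px[f],
                          key=lambda h: (h[2] - cx) ** 2 + (h[3] - cy) ** 2)
            assert (nearest[0], nearest[1]) == (t.kind, t.map_id)
            checked += 1
        assert checked >= 10


class TestScaleModelFit:
    def test_constant_scale_zero_pan(self):
        g = flat_gamma(np.zeros(20))
        model = fit_scale_model([(f, 400.0) for f in range(0, 21, 2)], g)
        np.testing.assert_allclose(model.s_fit, 400.0, atol=1e-6)
        assert model.residual < 1e-6

    def test_noiseless_parameter_recovery(self, run_clean):
        tr = run_clean.truth
        g = flat_gamma(tr.camera_gamma)
        frames = np.linspace(0, run_clean.config.n_frames - 1, 10).astype(int)
        model = fit_scale_model([(int(f), float(tr.scale_true[f])) for f in frames], g)
        assert abs(model.A - 400.0) / 400.0 < 0.01
        assert abs(model.alpha0 - (-0.2)) < 0.02

    def test_too_few_supporting_points(self):
        with pytest.raises(CalibrationError, match="supporting points"):
            fit_scale_model([(0, 400.0), (5, 390.0)], flat_gamma(np.zeros(10)))

    def test_fit_invariant_to_frame_offset(self, run_clean):
        """Prepending a zero-pan stretch must not change the fitted amplitude."""
        tr = run_clean.truth
        frames = np.linspace(0, run_clean.config.n_frames - 1, 8).astype(int)
        samples = [(int(f), float(tr.scale_true[f])) for f in frames]
        m0 = fit_scale_model(samples, flat_gamma(tr.camera_gamma))
        pad = 10
        g_pad = flat_gamma(np.concatenate([np.zeros(pad), tr.camera_gamma]))
        m1 = fit_scale_model([(f + pad, s) for f, s in samples], g_pad)
        assert abs(m1.A - m0.A) / m0.A < 1e-3

    def test_fig8_shape_scale_peaks_where_angle_smallest(self, res_noisy):
        model = res_noisy.scale
        i_peak = int(np.argmax(model.s_fit))
        i_alpha = int(np.argmin(np.abs(model.alpha)))
        assert abs(i_peak - i_alpha) <= 2


class TestMeasureScaleSamples:
    def test_one_sample_per_frame_with_two_identified_holds(self, res_clean,
                                                            run_clean):
        samples = dict(res_clean.scale.s_meas)
        tr = run_clean.truth
        assert len(samples) > 50
        for f, s in samples.items():
            assert s == pytest.approx(tr.scale_true[f], abs=1e-6)
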