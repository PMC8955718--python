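import numpy as np
import pytest

from speedkin.contact_detection import (ContactError, ContactInterval,
                                        assign_contact_holds,
                                        contacts_from_speed, detect_contacts,
                                        hsv_segment_holds, sub_eps_span,
                                        time_between_holds)
from speedkin.scale_calibration import HoldTrack
from speedkin.synthetic import render_frame

FPS = 24.0


def dwell_curve(dwells, n, peak=4.0, rng=None, noise=0.0):
    """Smooth speed curve: zero plateaus at the given frame spans, bells between."""
    v = np.full(n, peak, dtype=float)
    for lo, hi in dwells:
        v[lo:hi + 1] = 0.0
        ramp = 6
        for k in range(1, ramp):
            u = k / ramp
            bell = peak * (3 * u ** 2 - 2 * u ** 3)
            if lo - k >= 0:
                v[lo - k] = min(v[lo - k], bell)
            if hi + k < n:
                v[hi + k] = min(v[hi + k], bell)
    if rng is not None and noise > 0:
        v = np.abs(v + rng.normal(0, noise, n))
    return v


class TestDetectContacts:
    def test_constant_speed_no_contacts(self):
        assert detect_contacts(np.full(100, 1.0), FPS, eps=0.2) == []

    def test_rectified_sine_zeros_detected(self):
        t = np.arange(0, 2 + 1 / FPS, 1 / FPS)
        speed = np.abs(np.sin(2 * np.pi * t / 2))  # zeros at t = 0, 1, 2 s
        ivs = detect_contacts(speed, FPS, eps=0.1)
        assert len(ivs) == 3
        centers = [(lo + hi) / 2 / FPS for lo, hi in ivs]
        for c, z in zip(centers, (0.0, 1.0, 2.0)):
            assert abs(c - z) <= 1 / FPS

    def test_plateau_recovered_on_clean_curve(self):
        v = dwell_curve([(30, 50)], 100)
        ivs = detect_contacts(v, FPS, eps=0.15)
        assert len(ivs) == 1
        lo, hi = ivs[0]
        assert lo <= 30 and hi >= 50
        assert 30 - lo <= 6 and hi - 50 <= 6

    @pytest.mark.parametrize("seed", range(4))
    def test_eps_monotonicity(self, seed):
        """Lowering eps never increases the number of detected intervals."""
        rng = np.random.default_rng(seed)
        v = dwell_curve([(20, 35), (60, 80), (110, 130)], 160,
                        rng=rng, noise=0.05)
        counts = [len(detect_contacts(v, FPS, eps=e))
                  for e in (0.5, 0.3, 0.2, 0.1, 0.05, 0.01)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_noise_wiggle_does_not_split_plateau(self):
        rng = np.random.default_rng(0)
        v = dwell_curve([(30, 60)], 120, rng=rng, noise=0.05)
        v[45] = 0.35  # isolated excursion above the hysteresis level
        assert len(detect_contacts(v, FPS, eps=0.15)) == 1

    def test_durations_nonnegative_and_bounded(self, res_noisy):
        total = {limb: 0.0 for limb in ("left_hand", "right_hand",
                                        "left_foot", "right_foot")}
        duration = res_noisy.n_frames / res_noisy.config.fps
        for c in res_noisy.contacts:
            assert c.duration > 0
            total[c.limb] += c.duration
        assert all(t <= duration for t in total.values())

    def test_sub_eps_span_inside_interval(self):
        v = dwell_curve([(30, 50)], 100)
        iv = detect_contacts(v, FPS, eps=0.15)[0]
        span = sub_eps_span(v, iv, 0.15)
        assert iv[0] <= span[0] <= span[1] <= iv[1]


class TestContactInterval:
    def test_release_must_follow_touch(self):
        with pytest.raises(ValueError):
            ContactInterval(limb="left_hand", t_touch=1.0, t_release=1.0)

    def test_wrapping_converts_frames_to_seconds(self):
        v = dwell_curve([(24, 48)], 100)
        out = contacts_from_speed("left_hand", v, FPS, eps=0.15)
        assert len(out) == 1
        assert out[0].t_touch == pytest.approx(out[0].sub_eps_start, abs=0.3)
        assert out[0].duration > 0.5


def _track(kind, map_id, center, n=10):
    t = HoldTrack(kind=kind, map_id=map_id)
    for f in range(n):
        t.frames.append(f)
        t.centers_px.append(center)
        t.widths_px.append(40.0)
        t.comp_px.append(center)
    return t


class TestAssignContactHolds:
    def test_limb_parked_on_hold_center(self):
        tracks = [_track("hand", 7, (300.0, 500.0)), _track("hand", 8, (400.0, 900.0))]
        limb = np.full((10, 2), (300.0, 500.0))
        ivs = [ContactInterval("left_hand", t_touch=0.1, t_release=0.3)]
        out = assign_contact_holds(ivs, limb, tracks, np.zeros(10), fps=FPS)
        assert out[0].hold_id == 7

    def test_far_limb_stays_unassigned(self):
        tracks = [_track("hand", 7, (300.0, 500.0))]
        limb = np.full((10, 2), (800.0, 500.0))
        ivs = [ContactInterval("left_hand", t_touch=0.1, t_release=0.3)]
        out = assign_contact_holds(ivs, limb, tracks, np.zeros(10),
                                   radius_px=60.0, fps=FPS)
        assert out[0].hold_id is None

    def test_synthetic_ids_equal_dwell_schedule(self, run_noisy, res_noisy):
        truth = {(l, round(t0, 1)): h
                 for l, h, t0, t1 in run_noisy.truth.dwell_intervals}
        for limb in ("left_hand", "right_hand", "left_foot", "right_foot"):
            td = sorted((t0, h) for (l, h, t0, t1)
                        in run_noisy.truth.dwell_intervals if l == limb)
            det = sorted((c.t_touch, c.hold_id) for c in res_noisy.contacts
                         if c.limb == limb)
            assert [h for _, h in det] == [h for _, h in td]


class TestTimeBetweenHolds:
    CONTACTS = [
        ContactInterval("left_hand", 1.0, 1.4, hold_id=3),
        ContactInterval("right_hand", 2.5, 2.9, hold_id=4),
        ContactInterval("left_hand", 3.0, 3.4, hold_id=3),  # re-grab
    ]

    def test_first_touch_difference(self):
        assert time_between_holds(self.CONTACTS, 3, 4) == pytest.approx(1.5)

    def test_same_hold_zero(self):
        assert time_between_holds(self.CONTACTS, 3, 3) == 0.0

    def test_untouched_hold_raises(self):
        with pytest.raises(ContactError, match="never touched"):
            time_between_holds(self.CONTACTS, 3, 9)


class TestHsvSegmentation:
    def test_rendered_discs_recovered_within_one_pixel(self, run_clean):
        frame = 10
        img = render_frame(run_clean, frame)
        regions = hsv_segment_holds(img)
        H = run_clean.config.image_h
        truth = sorted((h[2], H - h[3]) for h in run_clean.truth.holds_px[frame])
        got = sorted(r.centroid_px for r in regions)
        assert len(got) == len(truth) > 0
        for (tx, ty), (gx, gy) in zip(truth, got):
            assert abs(tx - gx) <= 1.0 and abs(ty - gy) <= 1.0

    def test_gray_image_no_regions(self):
        img = np.full((100, 100, 3), 128, dtype=np.uint8)
        assert hsv_segment_holds(img) == []

    def test_region_below_min_area_excluded(self):
        img = np.full((100, 100, 3), 128, dtype=np.uint8)
        img[50:53, 50:53] = (220, 30, 30)  # 9 px blob
        assert hsv_segment_holds(img, min_area=40, morph_radius=0) == []
        assert len(hsv_segment_holds(img, min_area=5, morph_radius=0)) == 1

    def test_invariant_to_spotlight_gradient(self, run_clean):
        frame = 10
        plain = hsv_segment_holds(render_frame(run_clean, frame))
        lit = hsv_segment_holds(render_frame(run_clean, frame, spotlight=True))
        assert len(plain) == len(lit)
        for a, b in zip(sorted(r.centroid_px for r in plain),
                        sorted(r.centroid_px for r in lit)):
            assert abs(a[0] - b[0]) <= 1.0 and abs(a[1] - b[1]) <= 1.0

    def test_chalk_speckle_removed_by_morphology(self, run_clean):
        frame = 10
        img = render_frame(run_clean, frame, chalk=True, seed=4)
        regions = hsv_segment_holds(img)
        assert len(regions) == len(run_clean.truth.holds_px[frame])

    def test_non_rgb_input_rejected(self):
        with pytest.raises(ValueError):
            hsv_segment_holds(np.zeros((10, 10)))
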