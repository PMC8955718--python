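"""Synthetic speed-climb generator with full ground truth.

The generator emulates the study conditions the pipeline assumes: a climber
ascending the 15 m wall with zero-velocity dwell plateaus on numbered holds, a
tripod camera that rotates vertically to keep the athlete centred, perspective
captured by a per-frame affine projection with scale s_i = A cos(alpha_i),
Gaussian keypoint noise with i.i.d. dropout, and feature-match pairs between
consecutive frames carrying a controllable outlier fraction.

Model choices, stated once:

* The centre of gravity rises monotonically with a mildly modulated speed;
  limbs lead/lag it and dwell on holds while the COG traverses a fixed reach
  window (hands: [y_h - 0.85, y_h] m; feet, which reuse the hand holds a few
  moves lower: [y_h + 0.45, y_h + 1.3] m).  Moves between holds follow a
  quintic smoothstep, so limb velocity is exactly zero at both plateau edges —
  precisely the structure the contact detector assumes.
* The camera angle integrates the published recurrence
  alpha_{i+1} = (gamma_i/B) cos(alpha_i) + alpha_i, with gamma either derived
  from athlete tracking (gamma_i = s_i * dy_cog) or prescribed.
* Match pairs are static wall points displaced by exactly -gamma_i (y-up),
  plus outliers with horizontal displacement; keypoint noise does not apply
  to matches.

All ground-truth pixel quantities are y-up; files are written in native
(y-down) image coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io_formats
from .core import (BODY25_NAMES, LIMB_NAMES, RouteMap, load_anthropometric_table,
                   load_route_map)
from .io_formats import DetectionBox, MatchPair
from .kinematics import cog

LANE_CENTER_X_M = 1.5


class DwellScheduleError(RuntimeError):
    pass


@dataclass
class SynthConfig:
    """Generator knobs; the defaults are the study conditions."""

    fps: float = 24.0
    duration_s: float = 6.0
    sigma_px: float = 2.0          # keypoint noise std
    dropout: float = 0.05          # i.i.d. keypoint dropout rate
    outlier_frac: float = 0.2      # fraction of match pairs that are outliers
    scale_A: float = 400.0         # px/m
    gain_B: float = 5000.0         # px
    alpha0: float = -0.2           # rad
    image_w: int = 1280
    image_h: int = 720
    lane: str = "left"
    climb_speed_ms: float = 1.5
    speed_modulation: float = 0.15  # fractional sinusoidal speed variation
    start_y_m: float = 0.0
    mode: str = "climb"            # "climb" | "static"
    n_matches: int = 150
    hold_diameter_m: float = 0.10
    det_noise_frac: float = 0.5    # detection-centre noise = frac * sigma_px
    prescribed_alpha: Optional[np.ndarray] = None  # overrides the tracking camera
    dwell_schedule: Optional[List[Tuple[str, int, float, float]]] = None

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def cx(self) -> float:
        return self.image_w * (0.25 if self.lane == "left" else 0.75)

    @property
    def cy(self) -> float:
        return self.image_h / 2.0


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover."""

    t_s: np.ndarray
    cog_world: np.ndarray                   # (n, 2) m — anthropometric COG
    limb_world: Dict[str, np.ndarray]       # limb -> (n, 2) m
    dwell_intervals: List[Tuple[str, int, float, float]]
    camera_alpha: np.ndarray                # (n,) rad
    camera_gamma: np.ndarray                # (n-1,) px, y-up
    camera_y_m: np.ndarray                  # (n,) world height at image centre
    scale_true: np.ndarray                  # (n,) px/m
    cog_px: np.ndarray                      # (n, 2) y-up, noiseless
    keypoints_px: Dict[str, np.ndarray]     # name -> (n, 2) y-up, noiseless
    holds_px: List[List[Tuple[str, int, float, float, float]]]
    # per frame: (kind, id, x_px, y_px, w_px), y-up
    params: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "params": self.params,
            "dwell_intervals": self.dwell_intervals,
            "camera_alpha": self.camera_alpha.tolist(),
            "camera_gamma": self.camera_gamma.tolist(),
            "scale_true": self.scale_true.tolist(),
            "cog_world": self.cog_world.tolist(),
            "cog_px": self.cog_px.tolist(),
        }
        return json.dumps(payload)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: zero first and second derivative at both ends."""
    u = np.clip(u, 0.0, 1.0)
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u ** 2)


# ---------------------------------------------------------------------------
# world-space motion

def _cog_profile(cfg: SynthConfig) -> np.ndarray:
    """Nominal pelvis-centre height over time (m); monotone in climb mode."""
    t = np.arange(cfg.n_frames) / cfg.fps
    if cfg.mode == "static":
        return np.full_like(t, cfg.start_y_m)
    v0, m, period = cfg.climb_speed_ms, cfg.speed_modulation, 2.5
    y = cfg.start_y_m + v0 * (t + m * period / (2 * np.pi)
                              * (1.0 - np.cos(2 * np.pi * t / period)))
    return y


#: COG reach window (relative to the hold height) during which a limb dwells.
HAND_WINDOW = (-0.85, 0.0)
FOOT_WINDOW = (0.45, 1.30)

REST_OFFSET = {
    "left_hand": (-0.35, 0.55), "right_hand": (0.35, 0.55),
    "left_foot": (-0.20, -0.85), "right_foot": (0.20, -0.85),
}

_BLEND_S = 0.35  # transition time into the first / out of the last dwell


def build_dwell_schedule(cfg: SynthConfig, route_map: RouteMap,
                         y_cog: np.ndarray) -> List[Tuple[str, int, float, float]]:
    """Derive per-limb dwell intervals from the COG height profile.

    Hands alternate up the hand-hold ladder (left on odd ids); feet reuse the
    same ladder a few holds lower.  A limb dwells on hold h exactly while the
    COG is inside the limb's reach window around y_h.
    """
    t = np.arange(cfg.n_frames) / cfg.fps
    duration = t[-1]
    hand_holds = route_map.hand_holds()
    schedule: List[Tuple[str, int, float, float]] = []
    windows = {"left_hand": HAND_WINDOW, "right_hand": HAND_WINDOW,
               "left_foot": FOOT_WINDOW, "right_foot": FOOT_WINDOW}
    parity = {"left_hand": 1, "right_hand": 0, "left_foot": 1, "right_foot": 0}
    for limb in LIMB_NAMES:
        lo, hi = windows[limb]
        for h in hand_holds:
            if h.id % 2 != parity[limb]:
                continue
            enter_y, exit_y = h.y_m + lo, h.y_m + hi
            if enter_y <= y_cog[0] or exit_y >= y_cog[-1]:
                # incomplete dwell: touch or release falls outside the run
                continue
            t_enter = float(np.interp(enter_y, y_cog, t))
            t_exit = float(np.interp(exit_y, y_cog, t))
            if t_exit - t_enter >= 3.0 / cfg.fps:
                schedule.append((limb, h.id, t_enter, t_exit))
    _validate_schedule(schedule, duration)
    return schedule


def _validate_schedule(schedule: Sequence[Tuple[str, int, float, float]],
                       duration: float) -> None:
    by_limb: Dict[str, List[Tuple[float, float]]] = {}
    for limb, _, t0, t1 in schedule:
        if t1 > duration + 1e-9:
            raise DwellScheduleError(
                f"dwell on {limb} ends at {t1:.2f}s, beyond the {duration:.2f}s run")
        by_limb.setdefault(limb, []).append((t0, t1))
    for limb, ivs in by_limb.items():
        ivs.sort()
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise DwellScheduleError(f"overlapping dwells on {limb}")


def _limb_world(cfg: SynthConfig, route_map: RouteMap, y_cog: np.ndarray,
                schedule: Sequence[Tuple[str, int, float, float]],
                limb: str) -> np.ndarray:
    """World track of one limb endpoint: dwell plateaus joined by smoothsteps."""
    t = np.arange(cfg.n_frames) / cfg.fps
    off = np.array(REST_OFFSET[limb])
    base = np.column_stack([np.full_like(y_cog, LANE_CENTER_X_M), y_cog]) + off
    dwells = sorted([(t0, t1, route_map.hold(h, "hand"))
                     for l, h, t0, t1 in schedule if l == limb])
    if not dwells:
        return base
    pos = base.copy()
    hold_xy = [np.array([h.x_m, h.y_m]) for _, _, h in dwells]
    first_t0 = dwells[0][0]
    last_t1 = dwells[-1][1]
    # blend from COG-following into the first dwell
    w = _smoothstep((t - (first_t0 - _BLEND_S)) / _BLEND_S)
    pre = t < first_t0
    pos[pre] = (1 - w[pre, None]) * base[pre] + w[pre, None] * hold_xy[0]
    # dwells and moves
    for k, (t0, t1, _) in enumerate(dwells):
        on = (t >= t0) & (t <= t1)
        pos[on] = hold_xy[k]
        if k + 1 < len(dwells):
            nt0 = dwells[k + 1][0]
            mv = (t > t1) & (t < nt0)
            u = _smoothstep((t[mv] - t1) / (nt0 - t1))
            pos[mv] = hold_xy[k] + u[:, None] * (hold_xy[k + 1] - hold_xy[k])
    # blend out of the last dwell back to COG-following
    w = _smoothstep((t - last_t1) / _BLEND_S)
    post = t > last_t1
    pos[post] = (1 - w[post, None]) * hold_xy[-1] + w[post, None] * base[post]
    return pos


def _skeleton_world(cfg: SynthConfig, y_cog: np.ndarray,
                    limbs: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """World positions of all 25 BODY_25 keypoints from centre + limb tracks."""
    n = cfg.n_frames
    c = np.column_stack([np.full(n, LANE_CENTER_X_M), y_cog])

    def rel(dx: float, dy: float) -> np.ndarray:
        return c + np.array([dx, dy])

    neck = rel(0.0, 0.35)
    midhip = rel(0.0, -0.10)
    nose = rel(0.0, 0.50)
    rsho, lsho = neck + np.array([0.20, -0.02]), neck + np.array([-0.20, -0.02])
    rhip, lhip = midhip + np.array([0.13, 0.0]), midhip + np.array([-0.13, 0.0])
    rwri, lwri = limbs["right_hand"], limbs["left_hand"]
    rank = limbs["right_foot"] + np.array([0.03, 0.07])
    lank = limbs["left_foot"] + np.array([-0.03, 0.07])
    relb = 0.5 * (rsho + rwri) + np.array([0.08, 0.0])
    lelb = 0.5 * (lsho + lwri) + np.array([-0.08, 0.0])
    rkne = 0.5 * (rhip + rank) + np.array([0.08, 0.0])
    lkne = 0.5 * (lhip + lank) + np.array([-0.08, 0.0])
    pts = {
        "Nose": nose, "Neck": neck, "MidHip": midhip,
        "RShoulder": rsho, "LShoulder": lsho,
        "RElbow": relb, "LElbow": lelb,
        "RWrist": rwri, "LWrist": lwri,
        "RHip": rhip, "LHip": lhip,
        "RKnee": rkne, "LKnee": lkne,
        "RAnkle": rank, "LAnkle": lank,
        "RBigToe": limbs["right_foot"], "LBigToe": limbs["left_foot"],
        "RHeel": rank + np.array([-0.06, -0.05]),
        "LHeel": lank + np.array([0.06, -0.05]),
        "REye": nose + np.array([0.03, 0.03]), "LEye": nose + np.array([-0.03, 0.03]),
        "REar": nose + np.array([0.07, 0.0]), "LEar": nose + np.array([-0.07, 0.0]),
        "RSmallToe": limbs["right_foot"] + np.array([0.04, 0.0]),
        "LSmallToe": limbs["left_foot"] + np.array([-0.04, 0.0]),
    }
    return pts


# ---------------------------------------------------------------------------
# camera

def _camera(cfg: SynthConfig, track_y: np.ndarray
            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Angle, scale, shift and image-centre world height, frame by frame."""
    n = cfg.n_frames
    alpha = np.empty(n)
    s = np.empty(n)
    gamma = np.empty(n - 1)
    y_cam = np.empty(n)
    if cfg.prescribed_alpha is not None:
        alpha[:] = np.asarray(cfg.prescribed_alpha, dtype=float)
        s[:] = cfg.scale_A * np.cos(alpha)
        gamma[:] = cfg.gain_B * np.diff(alpha) / np.cos(alpha[:-1])
        y_cam[0] = track_y[0]
        for i in range(n - 1):
            y_cam[i + 1] = y_cam[i] + gamma[i] / s[i]
    else:
        alpha[0] = cfg.alpha0
        y_cam[:] = track_y
        for i in range(n - 1):
            s[i] = cfg.scale_A * np.cos(alpha[i])
            gamma[i] = s[i] * (track_y[i + 1] - track_y[i])
            alpha[i + 1] = (gamma[i] / cfg.gain_B) * np.cos(alpha[i]) + alpha[i]
        s[-1] = cfg.scale_A * np.cos(alpha[-1])
    return alpha, s, gamma, y_cam


def _project(cfg: SynthConfig, pts_m: np.ndarray, s: np.ndarray,
             y_cam: np.ndarray) -> np.ndarray:
    """World (n, 2) -> y-up pixel (n, 2) under the per-frame affine camera."""
    out = np.empty_like(pts_m)
    out[:, 0] = cfg.cx + s * (pts_m[:, 0] - LANE_CENTER_X_M)
    out[:, 1] = cfg.cy + s * (pts_m[:, 1] - y_cam)
    return out


# ---------------------------------------------------------------------------
# main entry

@dataclass
class SyntheticRun:
    truth: GroundTruth
    pose_frames: List[np.ndarray]       # per frame (n_people, 25, 3), native y-down
    matches: List[MatchPair]            # native y-down
    detections: List[DetectionBox]      # native y-down
    config: SynthConfig


def generate_run(cfg: SynthConfig, seed: int = 0,
                 out_dir=None, route_map: Optional[RouteMap] = None) -> SyntheticRun:
    """Generate one synthetic run (and optionally write its artifacts).

    The same (config, seed) pair always produces byte-identical artifacts.
    """
    rng = np.random.default_rng(seed)
    route_map = route_map if route_map is not None else load_route_map(lane=cfg.lane)
    n, H = cfg.n_frames, cfg.image_h
    t = np.arange(n) / cfg.fps

    y_nominal = _cog_profile(cfg)
    if cfg.mode == "climb":
        schedule = (cfg.dwell_schedule if cfg.dwell_schedule is not None
                    else build_dwell_schedule(cfg, route_map, y_nominal))
        if cfg.dwell_schedule is not None:
            _validate_schedule(schedule, t[-1])
        limbs = {limb: _limb_world(cfg, route_map, y_nominal, schedule, limb)
                 for limb in LIMB_NAMES}
    else:
        schedule = []
        limbs = {limb: np.column_stack(
            [np.full(n, LANE_CENTER_X_M), y_nominal]) + np.array(REST_OFFSET[limb])
            for limb in LIMB_NAMES}

    kp_world = _skeleton_world(cfg, y_nominal, limbs)
    table = load_anthropometric_table()
    cog_world = np.array([
        cog({k: kp_world[k][i] for k in kp_world}, table) for i in range(n)])

    alpha, s, gamma, y_cam = _camera(cfg, cog_world[:, 1])

    kp_px = {name: _project(cfg, pts, s, y_cam) for name, pts in kp_world.items()}
    cog_px = _project(cfg, cog_world, s, y_cam)

    # --- pose JSON records (noise + dropout, native y-down)
    pose_frames: List[np.ndarray] = []
    for i in range(n):
        rec = np.zeros((25, 3))
        for k, name in enumerate(BODY25_NAMES):
            if rng.uniform() < cfg.dropout:
                continue
            x, y_up = kp_px[name][i]
            x += rng.normal(0.0, cfg.sigma_px) if cfg.sigma_px > 0 else 0.0
            y_up += rng.normal(0.0, cfg.sigma_px) if cfg.sigma_px > 0 else 0.0
            rec[k] = (x, H - y_up, round(rng.uniform(0.5, 0.99), 3))
        pose_frames.append(rec[None, :, :])

    # --- hold detections (native y-down)
    det_sigma = cfg.det_noise_frac * cfg.sigma_px
    detections: List[DetectionBox] = []
    holds_px: List[List[Tuple[str, int, float, float, float]]] = []
    margin = 20.0
    for i in range(n):
        visible = []
        for h in route_map.holds:
            px = cfg.cx + s[i] * (h.x_m - LANE_CENTER_X_M)
            py = cfg.cy + s[i] * (h.y_m - y_cam[i])
            w = cfg.hold_diameter_m * s[i]
            if not (margin <= px <= cfg.image_w - margin
                    and margin <= py <= H - margin):
                continue
            visible.append((h.kind, h.id, float(px), float(py), float(w)))
            nx = px + (rng.normal(0.0, det_sigma) if det_sigma > 0 else 0.0)
            ny = py + (rng.normal(0.0, det_sigma) if det_sigma > 0 else 0.0)
            detections.append(DetectionBox(
                frame=i, class_label=h.kind, cx_px=float(nx),
                cy_px=float(H - ny), w_px=float(w), h_px=float(w),
                confidence=round(float(rng.uniform(0.75, 0.99)), 3)))
        holds_px.append(visible)

    # --- match pairs (native y-down; inliers displaced exactly by the shift)
    matches: List[MatchPair] = []
    n_out = int(round(cfg.n_matches * cfg.outlier_frac))
    n_in = cfg.n_matches - n_out
    for i in range(1, n):
        g = gamma[i - 1]
        xs = rng.uniform(0, cfg.image_w, n_in)
        ys = rng.uniform(0, H, n_in)
        for x, y in zip(xs, ys):
            # camera up by g (y-up) => content moves down => native y grows by g
            matches.append(MatchPair(frame=i, p_prev=(float(x), float(y)),
                                     p_curr=(float(x), float(y + g))))
        for _ in range(n_out):
            x, y = rng.uniform(0, cfg.image_w), rng.uniform(0, H)
            dx = rng.choice([-1, 1]) * rng.uniform(8.0, 40.0)
            dy = rng.uniform(-40.0, 40.0)
            matches.append(MatchPair(frame=i, p_prev=(float(x), float(y)),
                                     p_curr=(float(x + dx), float(y + dy))))

    truth = GroundTruth(
        t_s=t, cog_world=cog_world, limb_world=limbs,
        dwell_intervals=schedule, camera_alpha=alpha, camera_gamma=gamma,
        camera_y_m=y_cam, scale_true=s, cog_px=cog_px,
        keypoints_px=kp_px, holds_px=holds_px,
        params={"A": cfg.scale_A, "B": cfg.gain_B, "alpha0": cfg.alpha0,
                "fps": cfg.fps, "sigma_px": cfg.sigma_px,
                "dropout": cfg.dropout, "outlier_frac": cfg.outlier_frac})

    run = SyntheticRun(truth=truth, pose_frames=pose_frames,
                       matches=matches, detections=detections, config=cfg)
    if out_dir is not None:
        write_run(run, out_dir)
    return run


def write_run(run: SyntheticRun, out_dir) -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_pose_sequence(run.pose_frames, out / "pose")
    io_formats.write_matches(run.matches, out / "matches.csv")
    io_formats.write_detections(run.detections, out / "detections.csv")
    (out / "truth.json").write_text(run.truth.to_json())
    return {"pose": out / "pose", "matches": out / "matches.csv",
            "detections": out / "detections.csv", "truth": out / "truth.json"}


# ---------------------------------------------------------------------------
# rendering (fixture for the HSV segmenter)

def render_frame(run: SyntheticRun, frame: int, chalk: bool = False,
                 spotlight: bool = False, seed: int = 0) -> np.ndarray:
    """Render one frame: gray wall, saturated red hold discs, optional white
    chalk speckle and a vertical spotlight brightness gradient.

    The spotlight multiplies all channels, shifting HSV value but leaving hue
    untouched.  Returns an (H, W, 3) uint8 RGB image in native orientation.
    """
    cfg = run.config
    H, W = cfg.image_h, cfg.image_w
    img = np.full((H, W, 3), 120.0)
    yy, xx = np.mgrid[0:H, 0:W]
    for kind, hid, x_up, y_up, w in run.truth.holds_px[frame]:
        r = max(w / 2.0, 3.0)
        cx, cy = x_up, H - y_up  # native row coordinate
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        img[disc] = (210.0, 30.0, 25.0)
    if chalk:
        rng = np.random.default_rng(seed)
        spots = rng.uniform(size=(H, W)) < 0.002
        img[spots] = (235.0, 235.0, 235.0)
    if spotlight:
        grad = (0.65 + 0.35 * (1.0 - yy / H))[..., None]
        img = img * grad
    return np.clip(np.round(img), 0, 255).astype(np.uint8)
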