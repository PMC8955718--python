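"""Pixel-to-metric scale calibration from detected holds.

Because the camera only rotates, the scale s_i (px/m) changes smoothly over a
run: it peaks when the optical axis is perpendicular to the wall and falls off
toward the ends.  Direct scale measurements come from pairs of identified
holds — the pixel distance between two holds divided by their known route-map
distance, averaged over the x and y directions:

    s = 1/2 (|dx_px| / |dx_m| + |dy_px| / |dy_m|)

A geometric model ties the per-frame scale to the camera angle alpha_i,

    s_i = A cos(alpha_i),      alpha_{i+1} = (gamma_i / B) cos(alpha_i) + alpha_i,

with amplitude A (px/m), angle gain B (px) and start angle alpha_0 the three
free parameters; the camera's focal length, distance and pixel pitch are not
separately identifiable and are never reported individually.  The model is
fitted to the sparse measured samples by bounded nonlinear least squares with
a multi-start over the (non-convex) start angle.

All pixel coordinates here are y-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .camera_motion import CameraTrajectory
from .core import RouteMap
from .io_formats import DetectionBox

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    pass


@dataclass
class HoldTrack:
    """One physical hold tracked across frames (y-up pixel centres)."""

    kind: str
    frames: List[int] = field(default_factory=list)
    centers_px: List[Tuple[float, float]] = field(default_factory=list)
    widths_px: List[float] = field(default_factory=list)
    comp_px: List[Tuple[float, float]] = field(default_factory=list)  # pan-compensated
    map_id: Optional[int] = None

    @property
    def first_seen(self) -> int:
        return self.frames[0]

    @property
    def last_seen(self) -> int:
        return self.frames[-1]

    def mean_comp(self) -> Tuple[float, float]:
        arr = np.asarray(self.comp_px)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def center_at(self, frame: int) -> Optional[Tuple[float, float]]:
        try:
            return self.centers_px[self.frames.index(frame)]
        except ValueError:
            return None


@dataclass
class ScaleModel:
    """Fitted scale model: s_i = A cos(alpha_i)."""

    A: float
    B: float
    alpha0: float
    alpha: np.ndarray
    s_fit: np.ndarray
    s_meas: List[Tuple[int, float]]
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("scale amplitude A must be positive")

    def s_at(self, frame) -> np.ndarray:
        return np.asarray(self.s_fit)[np.asarray(frame, dtype=int)]


# ---------------------------------------------------------------------------
# Eq. 1 — direct pairwise scale

def pairwise_scale(holdA_px: Sequence[float], holdB_px: Sequence[float],
                   holdA_m: Sequence[float], holdB_m: Sequence[float]) -> float:
    """Scale (px/m) from one hold pair: mean of the two directional ratios.

    Falls back to the single usable axis (logged) when the map distance
    vanishes along the other one.
    """
    dx_px = abs(holdB_px[0] - holdA_px[0])
    dy_px = abs(holdB_px[1] - holdA_px[1])
    dx_m = abs(holdB_m[0] - holdA_m[0])
    dy_m = abs(holdB_m[1] - holdA_m[1])
    ratios = []
    if dx_m > 0:
        ratios.append(dx_px / dx_m)
    if dy_m > 0:
        ratios.append(dy_px / dy_m)
    if not ratios:
        raise CalibrationError("hold pair has zero map distance in both axes")
    if len(ratios) == 1:
        logger.debug("pairwise_scale: single-axis fallback used")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Eq. 3 — angle recurrence

def iterate_alpha(gamma_px: np.ndarray, B: float, alpha0: float) -> np.ndarray:
    """Integrate the camera angle: alpha_{i+1} = (gamma_i/B) cos(alpha_i) + alpha_i.

    Returns one angle per frame (len(gamma) + 1), starting at alpha0.
    """
    if B == 0:
        raise ValueError("angle gain B must be nonzero")
    gamma = np.asarray(gamma_px, dtype=float)
    alpha = np.empty(len(gamma) + 1)
    alpha[0] = alpha0
    for i, g in enumerate(gamma):
        alpha[i + 1] = (g / B) * np.cos(alpha[i]) + alpha[i]
    return alpha


# ---------------------------------------------------------------------------
# hold tracking and identification

def track_holds(detections: Sequence[DetectionBox], gamma: CameraTrajectory,
                gate_px: float = 60.0) -> List[HoldTrack]:
    """Link detection boxes across frames into per-hold tracks.

    Uses pan-compensated nearest-neighbour association: a box at frame i is
    compared against each live track's last compensated centre (y + cumulative
    camera shift), which is stationary for a wall-fixed hold.
    """
    by_frame: Dict[int, List[DetectionBox]] = {}
    for b in detections:
        by_frame.setdefault(b.frame, []).append(b)
    cum = gamma.cumulative_px
    tracks: List[HoldTrack] = []
    for f in sorted(by_frame):
        shift = cum[min(f, len(cum) - 1)]
        for box in by_frame[f]:
            comp = (box.cx_px, box.cy_px + shift)
            best, best_d = None, gate_px
            for tr in tracks:
                if tr.kind != box.class_label:
                    continue
                last = tr.comp_px[-1]
                d = float(np.hypot(last[0] - comp[0], last[1] - comp[1]))
                if d < best_d:
                    best, best_d = tr, d
            if best is None:
                best = HoldTrack(kind=box.class_label)
                tracks.append(best)
            best.frames.append(f)
            best.centers_px.append((box.cx_px, box.cy_px))
            best.widths_px.append(box.w_px)
            best.comp_px.append(comp)
    return tracks


def _ratio_profile(y: np.ndarray, x: np.ndarray):
    """Scale-invariant descriptors of a hold ladder: dy ratios and dx/dy slopes."""
    dy = np.diff(y)
    dx = np.diff(x)
    ratios = dy[1:] / dy[:-1]
    slopes = dx / dy
    return ratios, slopes


def identify_holds(tracks: List[HoldTrack], route_map: RouteMap,
                   kind: str = "hand") -> List[HoldTrack]:
    """Assign route-map ids to tracked holds by inter-hold distance matching.

    Tracks of the given kind are ordered by compensated height; the sequence
    of consecutive-distance ratios (and x/y slopes) is slid along the route
    map's own sequence, and the contiguous alignment minimising the summed
    squared residuals wins.  Modifies ``map_id`` in place and returns the
    identified tracks bottom-to-top.
    """
    sel = sorted((t for t in tracks if t.kind == kind),
                 key=lambda t: t.mean_comp()[1])
    if len(sel) < 2:
        raise CalibrationError("insufficient holds for calibration (need >= 2 tracks)")
    holds = route_map.hand_holds() if kind == "hand" else route_map.foot_holds()
    if len(sel) > len(holds):
        raise CalibrationError("more tracks than route-map holds")
    ty = np.array([t.mean_comp()[1] for t in sel])
    tx = np.array([t.mean_comp()[0] for t in sel])
    my = np.array([h.y_m for h in holds])
    mx = np.array([h.x_m for h in holds])

    if len(sel) == 2:
        # ratios undefined; anchor by slope alone
        t_slope = (tx[1] - tx[0]) / (ty[1] - ty[0])
        costs = [(t_slope - (mx[j + 1] - mx[j]) / (my[j + 1] - my[j])) ** 2
                 for j in range(len(holds) - 1)]
        offset = int(np.argmin(costs))
    else:
        t_r, t_s = _ratio_profile(ty, tx)
        best_cost, offset = np.inf, 0
        for j in range(len(holds) - len(sel) + 1):
            m_r, m_s = _ratio_profile(my[j:j + len(sel)], mx[j:j + len(sel)])
            cost = float(np.sum((t_r - m_r) ** 2) + np.sum((t_s - m_s) ** 2))
            if cost < best_cost:
                best_cost, offset = cost, j
    for k, tr in enumerate(sel):
        tr.map_id = holds[offset + k].id
    return sel


def track_and_identify_holds(detections: Sequence[DetectionBox],
                             gamma: CameraTrajectory, route_map: RouteMap,
                             gate_px: float = 60.0) -> List[HoldTrack]:
    """Full tracking + identification for hand holds (foot tracks kept unassigned)."""
    tracks = track_holds(detections, gamma, gate_px=gate_px)
    identify_holds(tracks, route_map, kind="hand")
    return tracks


# ---------------------------------------------------------------------------
# supporting-point measurement and model fit

def measure_scale_samples(tracks: Sequence[HoldTrack], route_map: RouteMap,
                          n_frames: int) -> List[Tuple[int, float]]:
    """One scale sample per frame where >= 2 identified holds are visible.

    Uses the widest-separated pair (largest |dy_px|) to minimise the relative
    measurement error.
    """
    id_tracks = [t for t in tracks if t.map_id is not None]
    samples: List[Tuple[int, float]] = []
    for f in range(n_frames):
        present = [(t, t.center_at(f)) for t in id_tracks]
        present = [(t, c) for t, c in present if c is not None]
        if len(present) < 2:
            continue
        best_pair, best_dy = None, -1.0
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                dy = abs(present[i][1][1] - present[j][1][1])
                if dy > best_dy:
                    best_dy, best_pair = dy, (present[i], present[j])
        (ta, ca), (tb, cb) = best_pair
        ha = route_map.hold(ta.map_id, ta.kind)
        hb = route_map.hold(tb.map_id, tb.kind)
        try:
            s = pairwise_scale(ca, cb, (ha.x_m, ha.y_m), (hb.x_m, hb.y_m))
        except CalibrationError:
            continue
        samples.append((f, s))
    return samples


def fit_scale_model(s_meas: Sequence[Tuple[int, float]], gamma: CameraTrajectory,
                    alpha0_starts: Sequence[float] = (-0.4, -0.2, 0.0, 0.2, 0.4),
                    B_starts: Sequence[float] = (2000.0, 5000.0, 20000.0),
                    ) -> ScaleModel:
    """Fit (A, B, alpha0) to measured scale samples by least squares.

    The loss is non-convex in the start angle, so the bounded trust-region
    solver is restarted from a small grid of (alpha0, B) initialisations and
    the best converged iterate wins.
    """
    samples = sorted(s_meas)
    if len(samples) < 3:
        raise CalibrationError("need >= 3 supporting points to fit the scale model")
    frames = np.array([f for f, _ in samples], dtype=int)
    values = np.array([s for _, s in samples], dtype=float)
    if frames[-1] >= gamma.n_frames:
        raise CalibrationError("scale sample beyond camera trajectory")

    def residuals(theta: np.ndarray) -> np.ndarray:
        A, B, alpha0 = theta
        alpha = iterate_alpha(gamma.gamma_px, B, alpha0)
        return A * np.cos(alpha[frames]) - values

    A0 = float(values.max())
    # the camera cannot sweep more than half a turn over the run
    B_lo = max(10.0, float(np.abs(gamma.gamma_px).sum()) / np.pi)
    bounds = ([1e-3, B_lo, -1.2], [1e6, 1e8, 1.2])
    best = None
    for a0 in alpha0_starts:
        for b0 in B_starts:
            b0 = float(np.clip(b0, bounds[0][1], bounds[1][1]))
            try:
                sol = least_squares(residuals, x0=[A0, b0, a0], bounds=bounds,
                                    method="trf", xtol=1e-12, ftol=1e-12)
            except Exception as exc:  # pragma: no cover - solver pathologies
                logger.debug("scale fit start (%s, %s) failed: %s", a0, b0, exc)
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise CalibrationError("scale-model fit did not converge from any start")
    A, B, alpha0 = best.x
    alpha = iterate_alpha(gamma.gamma_px, B, alpha0)
    return ScaleModel(A=float(A), B=float(B), alpha0=float(alpha0),
                      alpha=alpha, s_fit=A * np.cos(alpha),
                      s_meas=[(int(f), float(s)) for f, s in samples],
                      residual=float(np.sqrt(2.0 * best.cost / len(values))))
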