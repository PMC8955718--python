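"""Per-frame vertical camera shift from feature-match pairs.

The recording camera sits on a tripod and only rotates vertically to keep the
athlete centred, so between consecutive frames every static wall feature moves
by a common vertical pixel offset.  Matched feature pairs are filtered down to
those static, purely-vertical displacements and averaged per frame into the
camera shift gamma_i (y-up convention: gamma > 0 means the camera panned up,
i.e. static content moved down in the image).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .io_formats import MatchPair

logger = logging.getLogger(__name__)


class NoStaticFeaturesError(RuntimeError):
    """Raised when no frame retains any inlier match."""


@dataclass
class CameraTrajectory:
    """Estimated vertical camera motion.

    ``gamma_px[i]`` is the shift between frames i and i+1 (length n-1);
    ``cumulative_px[i]`` the total shift accumulated up to frame i (length n,
    starting at 0).  ``filled`` flags frames whose shift was carried forward
    because no inlier survived.
    """

    gamma_px: np.ndarray
    n_inliers: np.ndarray
    filled: np.ndarray = field(default=None)  # type: ignore[assignment]
    cumulative_px: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gamma_px = np.asarray(self.gamma_px, dtype=float)
        self.n_inliers = np.asarray(self.n_inliers, dtype=int)
        if self.filled is None:
            self.filled = np.zeros(len(self.gamma_px), dtype=bool)
        if self.cumulative_px is None:
            self.cumulative_px = np.concatenate(
                [[0.0], np.cumsum(self.gamma_px)])

    @property
    def n_frames(self) -> int:
        return len(self.gamma_px) + 1


def filter_matches(pairs: Sequence[MatchPair], tol_px: float = 3.0,
                   mad_k: float = 3.0) -> List[MatchPair]:
    """Keep matches consistent with a purely vertical, common camera shift.

    Two-stage filter: first drop pairs with horizontal motion (|dx| > tol_px),
    then keep only pairs whose vertical displacement lies inside a robust
    median +/- k*MAD band, so isolated moving objects (the climber!) cannot
    bias the average.
    """
    if tol_px < 0:
        raise ValueError("tol_px must be >= 0")
    vertical = [m for m in pairs
                if abs(m.p_curr[0] - m.p_prev[0]) <= tol_px]
    if not vertical:
        return []
    dy = np.array([m.p_curr[1] - m.p_prev[1] for m in vertical])
    med = np.median(dy)
    mad = np.median(np.abs(dy - med))
    band = mad_k * 1.4826 * mad
    if band == 0.0:
        band = 1e-9  # all agree exactly; keep only those
    keep = np.abs(dy - med) <= band
    return [m for m, k in zip(vertical, keep) if k]


def estimate_shift(pairs: Sequence[MatchPair], n_frames: int,
                   tol_px: float = 3.0, mad_k: float = 3.0) -> CameraTrajectory:
    """Average filtered match displacements into a per-frame camera shift.

    Pairs are grouped by their (later) frame index; gamma_{f-1} = -mean(dy)
    of that frame's inliers (y-up: static content moving down <=> camera up).
    Frames without inliers carry the previous shift forward and are flagged.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    by_frame: Dict[int, List[MatchPair]] = {}
    for m in pairs:
        by_frame.setdefault(m.frame, []).append(m)

    gamma = np.zeros(n_frames - 1)
    n_inl = np.zeros(n_frames - 1, dtype=int)
    filled = np.zeros(n_frames - 1, dtype=bool)
    any_inlier = False
    last = 0.0
    for f in range(1, n_frames):
        inliers = filter_matches(by_frame.get(f, []), tol_px=tol_px, mad_k=mad_k)
        if inliers:
            dy = np.mean([m.p_curr[1] - m.p_prev[1] for m in inliers])
            last = -float(dy)
            n_inl[f - 1] = len(inliers)
            any_inlier = True
        else:
            filled[f - 1] = True
            logger.debug("frame %d: no inlier matches, carrying gamma forward", f)
        gamma[f - 1] = last
    if not any_inlier:
        raise NoStaticFeaturesError("no static features in any frame")
    return CameraTrajectory(gamma_px=gamma, n_inliers=n_inl, filled=filled)
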