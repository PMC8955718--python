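"""Hold-contact intervals from limb-speed curve sketching, plus the classical
HSV hold segmenter.

A limb parked on a hold has (camera-compensated) speed near zero, so each
contact shows up as a flat valley in the filtered limb-speed curve.  Candidate
local minima below a speed threshold are expanded outward to the neighbouring
inflection points of the curve: the descending-edge inflection marks the touch
and the ascending-edge inflection the release.  Inflections are sign changes
of the discrete second difference of the *filtered* curve; wiggles inside the
sub-threshold valley are ignored so sensor noise cannot shrink an interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import color as skcolor
from skimage import measure, morphology

from .scale_calibration import HoldTrack

logger = logging.getLogger(__name__)


class ContactError(RuntimeError):
    pass


@dataclass
class ContactInterval:
    """One limb-on-hold episode (times in seconds)."""

    limb: str
    t_touch: float
    t_release: float
    hold_id: Optional[int] = None
    hold_kind: str = "hand"
    sub_eps_start: Optional[float] = None
    sub_eps_end: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_release <= self.t_touch:
            raise ValueError("t_release must exceed t_touch")

    @property
    def duration(self) -> float:
        return self.t_release - self.t_touch


@dataclass(frozen=True)
class HoldRegion:
    """A segmented hold candidate in one image."""

    centroid_px: Tuple[float, float]  # (x, y)
    area_px2: float
    mean_intensity: float
    bbox: Tuple[int, int, int, int]   # (min_row, min_col, max_row, max_col)


# ---------------------------------------------------------------------------
# contact detection from the speed curve

def _inflections(speed: np.ndarray) -> np.ndarray:
    """Sub-frame positions where the discrete second difference changes sign.

    A sign change of d2 between windows centred at i+1 and i+2 locates the
    inflection between those samples; the half-integer i+1.5 is returned so
    callers can round toward the contact (tighter boundaries, no systematic
    one-frame widening).
    """
    d2 = np.diff(speed, 2)
    s = np.sign(d2)
    # ignore exact zeros by carrying the previous sign
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    return np.where(s[1:] * s[:-1] < 0)[0] + 1.5


def detect_contacts(speed: np.ndarray, fps: float, eps: float = 0.15,
                    hysteresis: float = 2.0,
                    move_frac: float = 0.15) -> List[Tuple[int, int]]:
    """Contact frame intervals from a filtered limb-speed series (m/s).

    Returns merged ``(start, end)`` frame pairs, end inclusive.  Candidate
    valleys are the connected sub-``eps`` regions (each containing at least
    one local minimum); every valley is first extended outward while the
    speed stays below ``hysteresis * eps`` — so noise wiggles riding on a
    plateau can neither split a contact nor stop the boundary search early —
    and then expanded to the last preceding inflection with negative slope
    and the first following inflection with positive slope.  The boundary
    search stops at the adjacent major maximum (the next event's domain);
    an edge without an inflection — a pure concave arch, or the series end —
    keeps the hysteresis edge as its boundary.
    """
    v = np.asarray(speed, dtype=float)
    n = len(v)
    if n < 3:
        return []
    slope = np.gradient(v)
    infl = _inflections(v)
    h_eps = hysteresis * eps

    def _cap_left(lo: int) -> int:
        for k in range(lo - 1, 0, -1):
            if v[k] > h_eps and v[k] >= v[k - 1] and v[k] >= v[k + 1]:
                return k
        return 0

    def _cap_right(hi: int) -> int:
        for k in range(hi + 1, n - 1):
            if v[k] > h_eps and v[k] >= v[k - 1] and v[k] >= v[k + 1]:
                return k
        return n - 1

    below = v < eps
    intervals: List[Tuple[int, int]] = []
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        # hysteresis extension of the valley
        lo = i
        while lo > 0 and v[lo - 1] < h_eps:
            lo -= 1
        hi = j
        while hi + 1 < n and v[hi + 1] < h_eps:
            hi += 1
        # a boundary inflection must sit on a real speed edge (above the
        # hysteresis level); pre-/post-ringing of the zero-phase filter puts
        # spurious near-zero inflections just outside the plateau
        left = lo
        for km in infl[(infl <= lo + 0.5) & (infl >= _cap_left(lo))][::-1]:
            k = int(np.ceil(km))  # round toward the contact
            if slope[int(np.floor(km))] < 0 and v[k] >= h_eps:
                left = k
                break
        right = hi
        for km in infl[(infl >= hi - 0.5) & (infl <= _cap_right(hi))]:
            k = int(np.floor(km))
            if slope[int(np.ceil(km))] > 0 and v[k] >= h_eps:
                right = k
                break
        if right <= left:  # degenerate (kink) valley: keep the hysteresis span
            left, right = lo, hi
        if right > left:
            intervals.append((left, right))
        i = hi + 1

    # merge overlapping candidates; two contacts are distinct only if the limb
    # actually travelled between them, i.e. the speed in the gap reached a
    # fraction of the run's characteristic move speed
    merge_level = max(h_eps, move_frac * float(v.max()))
    intervals.sort()
    merged: List[Tuple[int, int]] = []
    for iv in intervals:
        if merged and (iv[0] <= merged[-1][1]
                       or v[merged[-1][1]:iv[0] + 1].max() < merge_level):
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(iv)
    return merged


def sub_eps_span(speed: np.ndarray, interval: Tuple[int, int],
                 eps: float) -> Optional[Tuple[int, int]]:
    """Contiguous sub-threshold span inside a detected interval (aux. output)."""
    v = np.asarray(speed, dtype=float)
    lo, hi = interval
    below = np.where(v[lo:hi + 1] < eps)[0]
    if len(below) == 0:
        return None
    return (lo + int(below[0]), lo + int(below[-1]))


def contacts_from_speed(limb: str, speed: np.ndarray, fps: float,
                        eps: float = 0.15) -> List[ContactInterval]:
    """Wrap frame intervals as ContactInterval records with times in seconds."""
    out = []
    for lo, hi in detect_contacts(speed, fps, eps=eps):
        sub = sub_eps_span(speed, (lo, hi), eps)
        out.append(ContactInterval(
            limb=limb, t_touch=lo / fps, t_release=hi / fps,
            sub_eps_start=None if sub is None else sub[0] / fps,
            sub_eps_end=None if sub is None else sub[1] / fps))
    return out


# ---------------------------------------------------------------------------
# hold association

def assign_contact_holds(intervals: Sequence[ContactInterval],
                         limb_track_px: np.ndarray,
                         tracks: Sequence[HoldTrack],
                         cumulative_px: np.ndarray,
                         radius_px: Optional[float] = None,
                         fps: float = 24.0) -> List[ContactInterval]:
    """Attach the nearest identified hold (pan-compensated) to each interval.

    Distance is evaluated at the interval midpoint frame between the limb
    keypoint and each hold track's compensated centre; beyond ``radius_px``
    (default 1.2 x the median detected hold width) the interval stays
    unassigned.
    """
    id_tracks = [t for t in tracks if t.map_id is not None]
    if radius_px is None:
        widths = [w for t in tracks for w in t.widths_px]
        radius_px = 1.2 * float(np.median(widths)) if widths else 50.0
    out = []
    for iv in intervals:
        mid = int(round(0.5 * (iv.t_touch + iv.t_release) * fps))
        mid = min(max(mid, 0), len(limb_track_px) - 1)
        p = limb_track_px[mid]
        comp = (p[0], p[1] + cumulative_px[min(mid, len(cumulative_px) - 1)])
        best, best_d = None, radius_px
        for tr in id_tracks:
            c = tr.mean_comp()
            d = float(np.hypot(c[0] - comp[0], c[1] - comp[1]))
            if d <= best_d:
                best, best_d = tr, d
        out.append(ContactInterval(
            limb=iv.limb, t_touch=iv.t_touch, t_release=iv.t_release,
            hold_id=None if best is None else best.map_id,
            hold_kind="hand" if best is None else best.kind,
            sub_eps_start=iv.sub_eps_start, sub_eps_end=iv.sub_eps_end))
    return out


def time_between_holds(contacts: Sequence[ContactInterval],
                       holdA: int, holdB: int, kind: str = "hand") -> float:
    """Elapsed time between the first touches of two holds (seconds)."""
    def first_touch(h: int) -> float:
        touches = [c.t_touch for c in contacts
                   if c.hold_id == h and c.hold_kind == kind]
        if not touches:
            raise ContactError(f"{kind} hold {h} was never touched")
        return min(touches)

    return first_touch(holdB) - first_touch(holdA)


# ---------------------------------------------------------------------------
# classical HSV segmentation

def hsv_segment_holds(image_rgb: np.ndarray,
                      hue_range: Tuple[float, float] = (0.95, 0.08),
                      sat_quantile: float = 0.90,
                      val_quantile: float = 0.10,
                      min_area: int = 40,
                      morph_radius: int = 2) -> List[HoldRegion]:
    """Segment saturated-colour holds in an RGB frame.

    The image is mapped to HSV; pixels inside the (wraparound-safe) hue band
    whose saturation/value exceed image-adaptive quantile thresholds form the
    mask, which is cleaned by morphological opening and closing before
    connected components below ``min_area`` are discarded.  The quantile
    thresholds make the segmenter robust to a moving spotlight, which shifts
    V but not H.
    """
    img = np.asarray(image_rgb)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    hsv = skcolor.rgb2hsv(img)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    lo, hi = hue_range
    hue_mask = (h >= lo) | (h <= hi) if lo > hi else (h >= lo) & (h <= hi)
    # the quantile adapts to lighting, the floor keeps desaturated (gray/chalk)
    # pixels out even when coloured holds cover only a small image fraction
    s_min = max(0.2, float(np.quantile(s, sat_quantile)))
    v_min = float(np.quantile(v, val_quantile))
    mask = hue_mask & (s >= s_min) & (v >= v_min)
    if morph_radius > 0:
        selem = morphology.disk(morph_radius)
        mask = morphology.opening(mask, selem)
        mask = morphology.closing(mask, selem)
    labels = measure.label(mask)
    gray = img.mean(axis=2)
    regions = []
    for r in measure.regionprops(labels, intensity_image=gray):
        if r.area < min_area:
            continue
        cy, cx = r.centroid
        regions.append(HoldRegion(
            centroid_px=(float(cx), float(cy)),
            area_px2=float(r.area),
            mean_intensity=float(r.intensity_mean),
            bbox=tuple(int(b) for b in r.bbox)))
    return regions
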