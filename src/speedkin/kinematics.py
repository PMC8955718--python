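"""Interpolation, joint angles, centre of gravity and metric velocity.

The centre of gravity (COG) of one frame is the segment-mass-weighted sum

    C = sum_b m_b (j_{p,b} + r_b x_b),        b = 1..12,

where x_b is the segment vector (distal - proximal keypoint), j_{p,b} its
proximal joint, m_b the segment's mass fraction and r_b its centre-of-mass
ratio.  Because the twelve mass fractions sum to one, C is an affine
combination of the keypoints and commutes with any affine image transform.

Metric velocity compensates the camera pan before scaling to world units:

    v_{y,i} = (C_{y,i+1} - C_{y,i} + gamma_i) * fps / s_i

(y-up pixels; gamma is vertical only, so the x component uses the plain pixel
difference).  Series are smoothed with a zero-phase Butterworth low-pass so
contact-event times read off the filtered curve are not lagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .camera_motion import CameraTrajectory
from .core import AnthropometricTable, REDUCED_NAMES, SkeletonFrame

logger = logging.getLogger(__name__)


class KinematicsError(RuntimeError):
    pass


@dataclass
class KeypointSeries:
    """Per-frame pixel tracks of the 19 keypoints, with a validity mask."""

    xy: Dict[str, np.ndarray]            # name -> (n, 2) float
    valid: Dict[str, np.ndarray]         # name -> (n,) bool (measured, not filled)
    interpolated: Dict[str, np.ndarray]  # name -> (n,) bool

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.xy.values())))


@dataclass
class JointAngleSeries:
    joint: str
    theta_deg: np.ndarray
    interpolated_mask: np.ndarray


@dataclass
class CogSeries:
    """Pixel and metric COG with camera-compensated velocity."""

    c_px: np.ndarray                     # (n, 2) y-up pixels
    v_ms: np.ndarray                     # (n-1, 2) m/s
    speed_ms: np.ndarray                 # (n-1,)
    c_m: Optional[np.ndarray] = None     # (n, 2) metres, when anchored


# ---------------------------------------------------------------------------
# gap filling

def frames_to_series(frames: Sequence[SkeletonFrame],
                     min_confidence: float = 0.1) -> KeypointSeries:
    """Stack skeleton frames into per-keypoint arrays; low confidence = missing."""
    n = len(frames)
    xy = {name: np.full((n, 2), np.nan) for name in REDUCED_NAMES}
    valid = {name: np.zeros(n, dtype=bool) for name in REDUCED_NAMES}
    for i, f in enumerate(frames):
        for name, (x, y, c) in f.keypoints.items():
            if c >= min_confidence and c > 0:
                xy[name][i] = (x, y)
                valid[name][i] = True
    interp = {name: np.zeros(n, dtype=bool) for name in REDUCED_NAMES}
    return KeypointSeries(xy=xy, valid=valid, interpolated=interp)


def interpolate_missing(series: KeypointSeries) -> KeypointSeries:
    """Fill missing samples: linear on interior gaps, nearest at the ends.

    Keypoints with fewer than two valid samples are left missing and logged.
    The returned mask marks every filled sample.
    """
    n = series.n_frames
    idx = np.arange(n)
    for name, pos in series.xy.items():
        ok = series.valid[name]
        if ok.sum() < 2:
            if not ok.all():
                logger.warning("keypoint %s: <2 valid samples, left missing", name)
            continue
        for d in range(2):
            pos[~ok, d] = np.interp(idx[~ok], idx[ok], pos[ok, d])
        series.interpolated[name] = ~ok
    return series


# ---------------------------------------------------------------------------
# angles

def joint_angle(a: Sequence[float], j: Sequence[float], b: Sequence[float]) -> float:
    """Angle at joint j between rays j->a and j->b, in degrees within [0, 180].

    Degenerate configurations (a == j or b == j) return NaN so they can be
    interpolated downstream.
    """
    u = np.asarray(a, dtype=float) - np.asarray(j, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(j, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


#: Joints reported by default: name -> (distal A, joint, distal B).
JOINT_DEFS: Dict[str, Tuple[str, str, str]] = {
    "right_elbow": ("RShoulder", "RElbow", "RWrist"),
    "left_elbow": ("LShoulder", "LElbow", "LWrist"),
    "right_knee": ("RHip", "RKnee", "RAnkle"),
    "left_knee": ("LHip", "LKnee", "LAnkle"),
}


def joint_angle_series(series: KeypointSeries, joint: str) -> JointAngleSeries:
    """Per-frame angle of one named joint, NaNs bridged by linear interpolation."""
    a_n, j_n, b_n = JOINT_DEFS[joint]
    n = series.n_frames
    theta = np.array([
        joint_angle(series.xy[a_n][i], series.xy[j_n][i], series.xy[b_n][i])
        for i in range(n)
    ])
    mask = (series.interpolated[a_n] | series.interpolated[j_n]
            | series.interpolated[b_n])
    bad = np.isnan(theta)
    if bad.any() and (~bad).sum() >= 2:
        idx = np.arange(n)
        theta[bad] = np.interp(idx[bad], idx[~bad], theta[~bad])
        mask = mask | bad
    return JointAngleSeries(joint=joint, theta_deg=theta, interpolated_mask=mask)


def trunk_inclination_series(series: KeypointSeries) -> JointAngleSeries:
    """Shoulder-hip ("SH") angle: mid-shoulder -> mid-hip line vs. vertical.

    This is one concrete reading of the shoulder/hip angle parameter — the
    inclination of the trunk axis against the wall's vertical axis, 0 deg for
    a perfectly upright trunk.
    """
    sh = 0.5 * (series.xy["RShoulder"] + series.xy["LShoulder"])
    hip = 0.5 * (series.xy["RHip"] + series.xy["LHip"])
    d = sh - hip
    theta = np.degrees(np.arctan2(np.abs(d[:, 0]), d[:, 1]))
    mask = (series.interpolated["RShoulder"] | series.interpolated["LShoulder"]
            | series.interpolated["RHip"] | series.interpolated["LHip"])
    return JointAngleSeries(joint="shoulder_hip", theta_deg=theta,
                            interpolated_mask=mask)


# ---------------------------------------------------------------------------
# centre of gravity

def cog(frame_or_xy, table: AnthropometricTable) -> np.ndarray:
    """COG of one frame: C = sum_b m_b (j_p + r_b (distal - proximal)).

    Accepts a SkeletonFrame or a name -> (x, y) mapping.  Raises when a
    segment endpoint is missing (which cannot happen after interpolation).
    """
    if isinstance(frame_or_xy, SkeletonFrame):
        pts = {n: np.array(v[:2]) for n, v in frame_or_xy.keypoints.items()}
    else:
        pts = {n: np.asarray(v, dtype=float) for n, v in frame_or_xy.items()}
    c = np.zeros(2)
    for seg in table.segments:
        try:
            p = pts[seg.proximal_kp]
            d = pts[seg.distal_kp]
        except KeyError as exc:
            raise KinematicsError(f"segment {seg.name}: missing endpoint {exc}")
        if np.isnan(p).any() or np.isnan(d).any():
            raise KinematicsError(f"segment {seg.name}: endpoint not available")
        c = c + seg.mass_frac * (p + seg.com_ratio * (d - p))
    return c


def cog_track(series: KeypointSeries, table: AnthropometricTable) -> np.ndarray:
    n = series.n_frames
    return np.array([
        cog({name: series.xy[name][i] for name in REDUCED_NAMES}, table)
        for i in range(n)
    ])


# ---------------------------------------------------------------------------
# velocity (camera compensated)

def velocity(track_px: np.ndarray, gamma: CameraTrajectory, s_px_per_m: np.ndarray,
             fps: float) -> np.ndarray:
    """Camera-compensated metric velocity of a y-up pixel track.

    v_{y,i} = (dy_i + gamma_i) * fps / s_i; the x component uses dx_i only
    (the tripod camera pans vertically).  ``s_px_per_m`` may be scalar or
    per-frame (length n or n-1).
    """
    p = np.asarray(track_px, dtype=float)
    n = len(p)
    if n < 2:
        raise KinematicsError("need >= 2 frames for a velocity")
    g = np.asarray(gamma.gamma_px, dtype=float)
    if len(g) != n - 1:
        raise KinematicsError("camera trajectory length mismatch")
    s_arr = np.asarray(s_px_per_m, dtype=float)
    if s_arr.ndim == 0:
        s = np.full(n - 1, float(s_arr))
    elif len(s_arr) in (n, n - 1):
        s = s_arr[: n - 1]
    else:
        raise KinematicsError("scale length must be n or n-1")
    if np.any(s <= 0):
        raise KinematicsError("scale must be positive")
    d = np.diff(p, axis=0)
    v = np.empty_like(d)
    v[:, 0] = d[:, 0] * fps / s
    v[:, 1] = (d[:, 1] + g) * fps / s
    return v


def cog_series(track_px: np.ndarray, gamma: CameraTrajectory,
               s_px_per_m, fps: float,
               anchor: Optional[Tuple[int, Tuple[float, float], Tuple[float, float]]] = None,
               ) -> CogSeries:
    """Bundle a COG pixel track with its metric velocity (and position).

    ``anchor`` optionally provides (frame, pixel_xy, world_xy) of a known
    landmark — typically an identified hold — fixing the absolute metric
    position; without it only velocities are metric.
    """
    v = velocity(track_px, gamma, s_px_per_m, fps)
    speed = np.linalg.norm(v, axis=1)
    c_m = None
    if anchor is not None:
        f0, px0, w0 = anchor
        n = len(track_px)
        s_arr = np.asarray(s_px_per_m, dtype=float)
        if s_arr.ndim == 0:
            s = np.full(n, float(s_arr))
        elif len(s_arr) == n:
            s = s_arr
        else:
            s = np.concatenate([s_arr[: n - 1], [s_arr[-1]]])
        # world height of the image point follows the camera: integrate gamma/s
        cam = np.concatenate([[0.0], np.cumsum(gamma.gamma_px / s[:-1])])
        c_m = np.empty_like(np.asarray(track_px, dtype=float))
        c_m[:, 0] = w0[0] + (track_px[:, 0] - px0[0]) / s
        c_m[:, 1] = w0[1] + (track_px[:, 1] - px0[1]) / s + (cam - cam[f0])
    return CogSeries(c_px=np.asarray(track_px, dtype=float), v_ms=v,
                     speed_ms=speed, c_m=c_m)


# ---------------------------------------------------------------------------
# filtering

def lowpass(series: np.ndarray, cutoff_hz: float, fps: float,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, no event-time lag).

    Series shorter than the filter warm-up are returned unfiltered (logged).
    """
    if fps <= 2 * cutoff_hz:
        raise ValueError("cutoff must be below the Nyquist frequency")
    x = np.asarray(series, dtype=float)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fps, output="sos")
    padlen = 6 * order
    if x.shape[0] <= padlen:
        logger.warning("series too short for low-pass warm-up; returned unfiltered")
        return x.copy()
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def auto_cutoff(series: np.ndarray, fps: float, energy_frac: float = 0.95,
                min_hz: float = 0.5) -> float:
    """Cutoff below which ``energy_frac`` of the (DC-removed) spectral energy lies."""
    x = np.asarray(series, dtype=float)
    if x.ndim > 1:
        x = np.linalg.norm(x, axis=1)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fps)
    total = spec.sum()
    if total == 0:
        return min_hz
    cum = np.cumsum(spec) / total
    k = int(np.searchsorted(cum, energy_frac))
    cutoff = float(freqs[min(k, len(freqs) - 1)])
    return float(np.clip(cutoff, min_hz, 0.49 * fps))
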