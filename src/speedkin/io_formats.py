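"""Readers and writers for pose JSON, detection/match CSVs and result exports.

Pose input follows the OpenPose BODY_25 JSON dialect: one JSON file per frame
with ``people[].pose_keypoints_2d`` holding 75 numbers (25 x (x, y, c)).
All tabular artifacts are plain CSV with fixed headers:

* detections: ``frame,class,x,y,w,h,confidence`` (box centre, pixels)
* matches:    ``frame,x_prev,y_prev,x_curr,y_curr`` (frame = later frame)
* route map:  ``id,kind,x_m,y_m``

Readers are total: malformed records degrade to logged skips, never a crash.
All file coordinates are native image pixels (y down).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import BODY25_NAMES, DROPPED_NAMES, REDUCED_NAMES, SkeletonFrame

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["frame", "class", "x", "y", "w", "h", "confidence"]
MATCH_COLUMNS = ["frame", "x_prev", "y_prev", "x_curr", "y_curr"]


@dataclass(frozen=True)
class DetectionBox:
    """One detector bounding box (centre + size, pixels)."""

    frame: int
    class_label: str
    cx_px: float
    cy_px: float
    w_px: float
    h_px: float
    confidence: float

    def __post_init__(self) -> None:
        if self.w_px <= 0 or self.h_px <= 0:
            raise ValueError("box size must be positive")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence outside [0, 1]")


@dataclass(frozen=True)
class MatchPair:
    """A feature matched between frame-1 and frame (pixel endpoints)."""

    frame: int
    p_prev: Tuple[float, float]
    p_curr: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError("match frame index must be >= 1")


class PoseReadError(RuntimeError):
    """Raised when a pose file cannot be read at all."""


# ---------------------------------------------------------------------------
# pose JSON

def _frame_index(path: Path, fallback: int) -> int:
    m = re.findall(r"(\d+)", path.stem)
    return int(m[-1]) if m else fallback


def read_pose_sequence(path) -> List[List[np.ndarray]]:
    """Read a directory (or single file) of per-frame BODY_25 pose JSON.

    Returns one entry per frame, in frame order; each entry is a list of
    people, each a ``(25, 3)`` float array of (x, y, confidence).  Frames with
    an empty ``people`` list or malformed content yield an empty list (the
    latter is logged).
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.json"), key=lambda f: _frame_index(f, 0))
    elif p.exists():
        files = [p]
    else:
        raise PoseReadError(f"pose path does not exist: {p}")
    frames: List[List[np.ndarray]] = []
    for i, f in enumerate(files):
        try:
            payload = json.loads(f.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise PoseReadError(f"unreadable pose JSON {f}: {exc}") from exc
        people: List[np.ndarray] = []
        for person in payload.get("people", []):
            raw = person.get("pose_keypoints_2d", [])
            if len(raw) != 75:
                logger.warning("%s: person with %d values skipped", f, len(raw))
                continue
            people.append(np.asarray(raw, dtype=float).reshape(25, 3))
        frames.append(people)
    return frames


def reduce_keypoints(record: np.ndarray, frame: int = 0) -> SkeletonFrame:
    """Reduce a 25-keypoint record to the 19 retained keypoints.

    Ears, eyes and small toes are dropped; everything else keeps its BODY_25
    name.  Out-of-range confidences are clipped into [0, 1].
    """
    arr = np.asarray(record, dtype=float)
    if arr.shape != (25, 3):
        raise ValueError(f"expected (25, 3) record, got {arr.shape}")
    kps = {}
    for name, (x, y, c) in zip(BODY25_NAMES, arr):
        if name in DROPPED_NAMES:
            continue
        kps[name] = (float(x), float(y), float(np.clip(c, 0.0, 1.0)))
    return SkeletonFrame(frame=frame, keypoints=kps)


def select_athlete(frames: List[List[np.ndarray]], side: str,
                   image_width_px: float) -> List[SkeletonFrame]:
    """Keep the highest-confidence skeleton on one lane half, per frame.

    Frames where the chosen half holds no skeleton yield an all-missing
    SkeletonFrame so downstream interpolation can bridge them.
    """
    out: List[SkeletonFrame] = []
    empty = {n: (0.0, 0.0, 0.0) for n in REDUCED_NAMES}
    half = image_width_px / 2.0
    for i, people in enumerate(frames):
        best = None
        best_conf = -1.0
        for person in people:
            valid = person[:, 2] > 0
            if not valid.any():
                continue
            mean_x = float(person[valid, 0].mean())
            on_side = mean_x < half if side == "left" else mean_x >= half
            if not on_side:
                continue
            conf = float(person[valid, 2].mean())
            if conf > best_conf:
                best, best_conf = person, conf
        if best is None:
            out.append(SkeletonFrame(frame=i, keypoints=dict(empty), side=side))
        else:
            sk = reduce_keypoints(best, frame=i)
            sk.side = side
            out.append(sk)
    return out


def write_pose_sequence(frames: Sequence[np.ndarray], out_dir) -> List[Path]:
    """Write per-frame (n_people, 25, 3) arrays as OpenPose-style JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, people in enumerate(frames):
        payload = {
            "version": 1.3,
            "people": [
                {"person_id": [-1],
                 "pose_keypoints_2d": [round(float(v), 4) for v in np.ravel(p)]}
                for p in people
            ],
        }
        path = out / f"frame_{i:06d}_keypoints.json"
        path.write_text(json.dumps(payload))
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# CSV artifacts

def read_detections(path) -> List[DetectionBox]:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections CSV missing columns {sorted(missing)}")
    df = df.rename(columns={"class": "class_label"})
    boxes = []
    for r in df.itertuples():
        try:
            boxes.append(DetectionBox(
                frame=int(r.frame), class_label=str(r.class_label),
                cx_px=float(r.x), cy_px=float(r.y),
                w_px=float(r.w), h_px=float(r.h),
                confidence=float(r.confidence)))
        except (TypeError, ValueError) as exc:
            logger.warning("detections row %s skipped: %s", r.Index, exc)
    return boxes


def write_detections(boxes: Sequence[DetectionBox], path) -> None:
    df = pd.DataFrame(
        [(b.frame, b.class_label, b.cx_px, b.cy_px, b.w_px, b.h_px, b.confidence)
         for b in boxes],
        columns=DETECTION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.4f")


def read_matches(path) -> List[MatchPair]:
    df = pd.read_csv(path)
    missing = set(MATCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"matches CSV missing columns {sorted(missing)}")
    pairs = []
    for r in df.itertuples():
        try:
            pairs.append(MatchPair(
                frame=int(r.frame),
                p_prev=(float(r.x_prev), float(r.y_prev)),
                p_curr=(float(r.x_curr), float(r.y_curr))))
        except (TypeError, ValueError) as exc:
            logger.warning("matches row %s skipped: %s", r.Index, exc)
    return pairs


def write_matches(pairs: Sequence[MatchPair], path) -> None:
    df = pd.DataFrame(
        [(m.frame, m.p_prev[0], m.p_prev[1], m.p_curr[0], m.p_curr[1])
         for m in pairs],
        columns=MATCH_COLUMNS)
    df.to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# coordinate convention

def flip_y(y_px, image_height_px: float):
    """Map native y-down pixels to y-up wall-aligned pixels (involution)."""
    return image_height_px - np.asarray(y_px, dtype=float)


# ---------------------------------------------------------------------------
# result export

def write_report(out_dir, *, parameters: Optional[pd.DataFrame] = None,
                 contacts: Optional[pd.DataFrame] = None,
                 angles: Optional[pd.DataFrame] = None,
                 cog: Optional[pd.DataFrame] = None,
                 camera: Optional[pd.DataFrame] = None,
                 scale: Optional[pd.DataFrame] = None,
                 summary: Optional[dict] = None) -> Dict[str, Path]:
    """Export computed series and run parameters as CSV (+ summary JSON).

    Column order is fixed by the incoming frames; floats are printed with
    enough digits that a read-back reproduces them to 1e-9.  Empty inputs
    yield headers-only files, and two identical runs export byte-identical
    files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out}: {exc}") from exc
    written: Dict[str, Path] = {}
    tables = {"parameters": parameters, "contacts": contacts, "angles": angles,
              "cog": cog, "camera": camera, "scale": scale}
    for name, df in tables.items():
        if df is None:
            continue
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.12g")
        written[name] = path
    if summary is not None:
        path = out / "run_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
        written["summary"] = path
    return written
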