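"""Section-wise comparison parameters and run synchronization.

The wall is split into sections delimited by hand holds (Start: holds 1-5,
Middle I: 6-8, Middle II: 6-12, End: 12-20 by default); each section is the
time window between the first touches of its boundary holds.  From the COG
velocity, the contact intervals and the trunk (shoulder-hip) angle the
per-run comparison parameter set is assembled: end time, per-section path
length / speed statistics / duration, whole-run path and speed, hand and foot
contact-time statistics, and trunk-angle statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contact_detection import ContactInterval

logger = logging.getLogger(__name__)


class SyncError(RuntimeError):
    pass


@dataclass(frozen=True)
class SectionDef:
    name: str
    start_hold: int
    end_hold: int

    def __post_init__(self) -> None:
        if self.start_hold >= self.end_hold:
            raise ValueError("section start hold must precede end hold")


DEFAULT_SECTIONS: Tuple[SectionDef, ...] = (
    SectionDef("start", 1, 5),
    SectionDef("middle_1", 6, 8),
    SectionDef("middle_2", 6, 12),
    SectionDef("end", 12, 20),
)


@dataclass
class SectionStats:
    name: str
    available: bool
    t_start_s: float = float("nan")
    t_end_s: float = float("nan")
    time_s: float = float("nan")
    path_m: float = float("nan")
    speed_mean_ms: float = float("nan")
    speed_std_ms: float = float("nan")
    speed_end_ms: float = float("nan")


@dataclass
class RunParameters:
    """The per-run comparison parameter set."""

    endtime_s: Optional[float]
    sections: List[SectionStats]
    path_m: float
    speed_mean_ms: float
    speed_std_ms: float
    contact_hands_mean_s: float
    contact_hands_std_s: float
    contact_feet_mean_s: float
    contact_feet_std_s: float
    sh_mean_deg: float
    sh_maxmin_deg: float
    sh_std_deg: float

    def to_frame(self) -> pd.DataFrame:
        row: Dict[str, float] = {
            "endtime_s": np.nan if self.endtime_s is None else self.endtime_s,
            "path_m": self.path_m,
            "speed_mean_ms": self.speed_mean_ms,
            "speed_std_ms": self.speed_std_ms,
            "contact_hands_mean_s": self.contact_hands_mean_s,
            "contact_hands_std_s": self.contact_hands_std_s,
            "contact_feet_mean_s": self.contact_feet_mean_s,
            "contact_feet_std_s": self.contact_feet_std_s,
            "sh_mean_deg": self.sh_mean_deg,
            "sh_maxmin_deg": self.sh_maxmin_deg,
            "sh_std_deg": self.sh_std_deg,
        }
        for s in self.sections:
            for key in ("time_s", "path_m", "speed_mean_ms", "speed_std_ms",
                        "speed_end_ms"):
                row[f"{s.name}_{key}"] = getattr(s, key) if s.available else np.nan
        return pd.DataFrame([row])


def first_touch_times(contacts: Sequence[ContactInterval],
                      kind: str = "hand") -> Dict[int, float]:
    out: Dict[int, float] = {}
    for c in contacts:
        if c.hold_id is None or c.hold_kind != kind:
            continue
        if c.hold_id not in out or c.t_touch < out[c.hold_id]:
            out[c.hold_id] = c.t_touch
    return out


def detect_start_time(speed_ms: np.ndarray, fps: float,
                      threshold_ms: float = 0.3, sustain_frames: int = 3
                      ) -> Optional[float]:
    """First time the COG speed exceeds the threshold for ``sustain_frames``."""
    above = np.asarray(speed_ms) > threshold_ms
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain_frames:
            return (i - sustain_frames + 1) / fps
    return None


def compute_parameters(speed_ms: np.ndarray,
                       contacts: Sequence[ContactInterval],
                       sh_deg: np.ndarray,
                       fps: float,
                       sections: Sequence[SectionDef] = DEFAULT_SECTIONS,
                       top_hold: int = 20,
                       start_threshold_ms: float = 0.3) -> RunParameters:
    """Assemble the comparison parameter set from computed series.

    ``speed_ms`` is the (filtered) COG speed on n-1 frame gaps; path lengths
    integrate it.  Sections whose boundary holds were never touched are
    marked unavailable.  The end time runs from the sustained-speed start
    trigger to the first touch of the top hold (None when either is missing).
    """
    speed = np.asarray(speed_ms, dtype=float)
    touches = first_touch_times(contacts, kind="hand")

    t_start = detect_start_time(speed, fps, start_threshold_ms)
    endtime = None
    if t_start is not None and top_hold in touches:
        endtime = touches[top_hold] - t_start

    section_stats: List[SectionStats] = []
    for sec in sections:
        if sec.start_hold not in touches or sec.end_hold not in touches:
            logger.info("section %s unavailable (boundary hold untouched)", sec.name)
            section_stats.append(SectionStats(name=sec.name, available=False))
            continue
        t0, t1 = touches[sec.start_hold], touches[sec.end_hold]
        i0, i1 = int(round(t0 * fps)), int(round(t1 * fps))
        i0 = max(0, min(i0, len(speed)))
        i1 = max(i0 + 1, min(i1, len(speed)))
        window = speed[i0:i1]
        section_stats.append(SectionStats(
            name=sec.name, available=True, t_start_s=t0, t_end_s=t1,
            time_s=t1 - t0,
            path_m=float(window.sum() / fps),
            speed_mean_ms=float(window.mean()),
            speed_std_ms=float(window.std()),
            speed_end_ms=float(window[-3:].mean())))

    hands = [c.duration for c in contacts if "hand" in c.limb]
    feet = [c.duration for c in contacts if "foot" in c.limb]
    sh = np.asarray(sh_deg, dtype=float)
    sh = sh[~np.isnan(sh)]

    def _stats(x: List[float]) -> Tuple[float, float]:
        if not x:
            return float("nan"), float("nan")
        return float(np.mean(x)), float(np.std(x))

    hm, hs = _stats(hands)
    fm, fs = _stats(feet)
    return RunParameters(
        endtime_s=endtime,
        sections=section_stats,
        path_m=float(speed.sum() / fps),
        speed_mean_ms=float(speed.mean()) if len(speed) else float("nan"),
        speed_std_ms=float(speed.std()) if len(speed) else float("nan"),
        contact_hands_mean_s=hm, contact_hands_std_s=hs,
        contact_feet_mean_s=fm, contact_feet_std_s=fs,
        sh_mean_deg=float(sh.mean()) if len(sh) else float("nan"),
        sh_maxmin_deg=float(sh.max() - sh.min()) if len(sh) else float("nan"),
        sh_std_deg=float(sh.std()) if len(sh) else float("nan"))


# ---------------------------------------------------------------------------
# run synchronization

@dataclass
class SyncResult:
    """Alignment of run A onto run B at a shared hold.

    ``shift_a``/``shift_b`` are subtracted from each run's times so the
    anchor-hold touch is t=0 in both; ``warp`` maps A's shifted times onto
    B's shifted axis through the shared hold-touch knots (identity when the
    runs share only the anchor).
    """

    at_hold: int
    shift_a: float
    shift_b: float
    knots_a: np.ndarray
    knots_b: np.ndarray

    def warp(self, t_a) -> np.ndarray:
        t = np.asarray(t_a, dtype=float)
        if len(self.knots_a) < 2:
            return t
        return np.interp(t, self.knots_a, self.knots_b)


def synchronize_runs(contacts_a: Sequence[ContactInterval],
                     contacts_b: Sequence[ContactInterval],
                     at_hold: int) -> SyncResult:
    """Time-align two runs at one hold, with a piecewise-linear hold warp."""
    ta = first_touch_times(contacts_a)
    tb = first_touch_times(contacts_b)
    shared = sorted(set(ta) & set(tb))
    if not shared:
        raise SyncError("runs share no touched holds")
    if at_hold not in ta or at_hold not in tb:
        raise SyncError(f"hold {at_hold} not touched in both runs")
    shift_a, shift_b = ta[at_hold], tb[at_hold]
    ka = np.array([ta[h] - shift_a for h in shared])
    kb = np.array([tb[h] - shift_b for h in shared])
    order = np.argsort(ka)
    return SyncResult(at_hold=at_hold, shift_a=shift_a, shift_b=shift_b,
                      knots_a=ka[order], knots_b=kb[order])
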