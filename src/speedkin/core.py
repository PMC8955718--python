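"""Domain types shared by every stage of the speed-climbing analysis.

The speed wall is standardized worldwide: 15 m high, 3 m per lane, leaning
5 degrees past vertical, with 20 hand holds and 11 foot holds bolted at fixed
route-map positions.  Coordinates on the wall are measured in metres along the
wall plane, y increasing upward.  Image coordinates are pixels; readers deliver
native y-down values and the pipeline flips to y-up before any kinematics, so
that positive vertical velocity always means "upward".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: BODY_25 keypoint names in OpenPose output order.
BODY25_NAMES: Tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

#: Keypoints discarded by the pipeline: ears, eyes and small toes.
DROPPED_NAMES: frozenset = frozenset(
    {"REye", "LEye", "REar", "LEar", "LSmallToe", "RSmallToe"}
)

#: The 19 keypoints actually used, in BODY_25 order.
REDUCED_NAMES: Tuple[str, ...] = tuple(
    n for n in BODY25_NAMES if n not in DROPPED_NAMES
)

LIMB_NAMES: Tuple[str, ...] = ("left_hand", "right_hand", "left_foot", "right_foot")


@dataclass(frozen=True)
class WallGeometry:
    """Standardized speed-wall dimensions.

    ``panel_count`` is stored for completeness only; no geometry is derived
    from it.
    """

    height_m: float = 15.0
    lane_width_m: float = 3.0
    overhang_deg: float = 5.0
    panel_count: int = 30

    def __post_init__(self) -> None:
        if self.height_m <= 0 or self.lane_width_m <= 0:
            raise ValueError("wall dimensions must be positive")
        if not 0.0 <= self.overhang_deg < 90.0:
            raise ValueError("overhang_deg must be in [0, 90)")


@dataclass(frozen=True)
class Hold:
    """One climbing hold at its route-map position (metres, wall plane)."""

    id: int
    kind: str  # "hand" | "foot"
    x_m: float
    y_m: float

    def __post_init__(self) -> None:
        if self.kind not in ("hand", "foot"):
            raise ValueError(f"unknown hold kind {self.kind!r}")


@dataclass
class RouteMap:
    """Ordered hold layout of one lane.

    Hand holds are numbered 1-20 bottom to top; foot holds carry their own
    1-11 numbering (kind distinguishes the two series).
    """

    holds: List[Hold]
    lane: str = "left"
    wall: WallGeometry = field(default_factory=WallGeometry)

    def __post_init__(self) -> None:
        for h in self.holds:
            if not (0.0 <= h.x_m <= self.wall.lane_width_m):
                raise ValueError(f"hold {h.kind} {h.id}: x_m outside lane")
            if not (0.0 <= h.y_m <= self.wall.height_m):
                raise ValueError(f"hold {h.kind} {h.id}: y_m outside wall")
        for kind in ("hand", "foot"):
            ids = [h.id for h in self.holds if h.kind == kind]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {kind} hold ids")
        hand = self.hand_holds()
        if any(b.y_m <= a.y_m for a, b in zip(hand, hand[1:])):
            raise ValueError("hand-hold heights must increase with id")

    def hand_holds(self) -> List[Hold]:
        return sorted((h for h in self.holds if h.kind == "hand"), key=lambda h: h.id)

    def foot_holds(self) -> List[Hold]:
        return sorted((h for h in self.holds if h.kind == "foot"), key=lambda h: h.id)

    def hold(self, hold_id: int, kind: str = "hand") -> Hold:
        for h in self.holds:
            if h.id == hold_id and h.kind == kind:
                return h
        raise KeyError(f"no {kind} hold {hold_id} in route map")


@dataclass(frozen=True)
class SegmentDef:
    """One body segment: mass fraction m_b and COM position ratio r_b.

    The segment centre of mass sits at ``proximal + com_ratio * (distal -
    proximal)``.
    """

    name: str
    proximal_kp: str
    distal_kp: str
    mass_frac: float
    com_ratio: float

    def violations(self) -> List[str]:
        out = []
        if not 0.0 < self.mass_frac < 1.0:
            out.append(f"{self.name}: mass_frac {self.mass_frac} outside (0, 1)")
        if not 0.0 < self.com_ratio < 1.0:
            out.append(f"{self.name}: com_ratio {self.com_ratio} outside (0, 1)")
        for kp in (self.proximal_kp, self.distal_kp):
            if kp not in REDUCED_NAMES:
                out.append(f"{self.name}: unknown keypoint {kp!r}")
        return out


@dataclass
class AnthropometricTable:
    """The 12-segment male body model used for the centre of gravity.

    Bilateral segments (arms, legs, feet) appear once per side, each carrying
    the per-side mass fraction, so the twelve fractions sum to one.
    """

    segments: List[SegmentDef]

    def mass_sum(self) -> float:
        return float(sum(s.mass_frac for s in self.segments))

    def segment(self, name: str) -> SegmentDef:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"missing segment {name!r}")


@dataclass
class ValidationReport:
    passed: bool
    violations: List[str] = field(default_factory=list)


def validate_table(table: AnthropometricTable) -> ValidationReport:
    """Check the anthropometric table: 12 segments, masses summing to 1.

    Returns a report listing every violation rather than raising.
    """
    violations: List[str] = []
    if len(table.segments) != 12:
        violations.append(f"12 segments required, got {len(table.segments)}")
    else:
        total = table.mass_sum()
        if abs(total - 1.0) > 1e-6:
            violations.append(f"mass sum != 1 (got {total:.6f})")
    for seg in table.segments:
        violations.extend(seg.violations())
    names = [s.name for s in table.segments]
    if len(names) != len(set(names)):
        violations.append("duplicate segment names")
    return ValidationReport(passed=not violations, violations=violations)


@dataclass
class SkeletonFrame:
    """The 19 retained keypoints of one athlete on one frame.

    ``keypoints`` maps each retained name to ``(x_px, y_px, confidence)``;
    a missing detection is encoded as confidence 0.
    """

    frame: int
    keypoints: Dict[str, Tuple[float, float, float]]
    side: str = "unassigned"  # "left" | "right" | "unassigned"

    def __post_init__(self) -> None:
        if set(self.keypoints) != set(REDUCED_NAMES):
            raise ValueError("SkeletonFrame requires exactly the 19 retained keypoints")
        for name, (_, _, c) in self.keypoints.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{name}: confidence {c} outside [0, 1]")

    def valid_names(self, min_confidence: float = 0.0) -> List[str]:
        return [n for n, (_, _, c) in self.keypoints.items() if c > min_confidence]


@dataclass
class RunConfig:
    """Tunable knobs of one analysis run."""

    fps: float = 24.0
    pixel_y_axis: str = "down"          # convention of the input files
    image_width_px: int = 1280
    image_height_px: int = 720
    vertical_match_tol_px: float = 3.0  # |dx| gate for static-feature pairs
    mad_k: float = 3.0                  # robust band half-width in MADs
    min_confidence: float = 0.1         # below this a keypoint counts as missing
    lowpass_cutoff_hz: object = 6.0     # Hz, or "auto" for spectral selection
    contact_speed_eps: float = 0.15     # m/s; limb counts as parked below this
    contact_radius_px: Optional[float] = None  # None -> 1.2 x median hold width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("vertical_match_tol_px", "mad_k", "min_confidence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_y_axis not in ("down", "up"):
            raise ValueError("pixel_y_axis must be 'down' or 'up'")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# bundled resources

def _data_path(name: str):
    return resources.files("speedkin.data").joinpath(name)


def load_anthropometric_table(path=None) -> AnthropometricTable:
    """Load a segment table (bundled male table by default)."""
    src = path if path is not None else _data_path("anthropometric_male.csv")
    df = pd.read_csv(src)
    segments = [
        SegmentDef(
            name=str(r.segment),
            proximal_kp=str(r.proximal_kp),
            distal_kp=str(r.distal_kp),
            mass_frac=float(r.mass_frac),
            com_ratio=float(r.com_ratio),
        )
        for r in df.itertuples()
    ]
    return AnthropometricTable(segments=segments)


def load_route_map(path=None, lane: str = "left") -> RouteMap:
    """Load a route map CSV (``id,kind,x_m,y_m``).

    The bundled default is a constructed, synthetic stand-in for the
    standardized competition layout: 20 hand and 11 foot holds over 15 m with
    realistic, non-uniform spacing.  User maps override it hold for hold.
    """
    src = path if path is not None else _data_path("route_map_synthetic.csv")
    df = pd.read_csv(src)
    holds = [
        Hold(id=int(r.id), kind=str(r.kind), x_m=float(r.x_m), y_m=float(r.y_m))
        for r in df.itertuples()
    ]
    return RouteMap(holds=holds, lane=lane)


# ---------------------------------------------------------------------------
# side assignment

def assign_side(frames: Sequence[SkeletonFrame], image_width_px: float,
                min_confidence: float = 0.0) -> List[SkeletonFrame]:
    """Assign each skeleton track to the left or right lane half.

    A frame votes left when the mean x of its valid keypoints falls left of
    the image centre; the whole track then takes the majority side so single
    noisy frames cannot flip it.  Frames without any valid keypoint stay
    unassigned and are logged.
    """
    votes = []
    for f in frames:
        names = f.valid_names(min_confidence)
        if not names:
            votes.append(None)
            logger.warning("frame %d: no valid keypoints, side unassigned", f.frame)
            continue
        mean_x = float(np.mean([f.keypoints[n][0] for n in names]))
        votes.append("left" if mean_x < image_width_px / 2.0 else "right")
    counted = [v for v in votes if v is not None]
    majority = None
    if counted:
        majority = "left" if counted.count("left") >= counted.count("right") else "right"
    out = []
    for f, v in zip(frames, votes):
        side = majority if v is not None else "unassigned"
        out.append(replace(f, side=side if side is not None else "unassigned"))
    return out
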