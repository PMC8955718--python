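"""End-to-end orchestration: artifacts in, comparison parameters out.

``analyze_run`` chains the stages: pose reduction and side selection, camera
shift estimation from match pairs, hold tracking/identification and scale
fitting from detections, COG and limb velocities with camera compensation,
zero-phase filtering, contact detection and hold association, and finally the
section parameter set.  Inputs may be in-memory objects (as produced by the
synthetic generator) or files via ``analyze_files``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import camera_motion, contact_detection, io_formats, kinematics, report
from . import scale_calibration as scal
from .core import (AnthropometricTable, RouteMap, RunConfig, load_anthropometric_table,
                   load_route_map)
from .io_formats import DetectionBox, MatchPair

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    config: RunConfig
    n_frames: int
    skeleton: kinematics.KeypointSeries
    gamma: camera_motion.CameraTrajectory
    tracks: List[scal.HoldTrack]
    scale: scal.ScaleModel
    cog: kinematics.CogSeries
    cog_speed_filt: np.ndarray
    cutoff_hz: float
    angles: Dict[str, kinematics.JointAngleSeries]
    limb_speed_filt: Dict[str, np.ndarray]
    contacts: List[contact_detection.ContactInterval]
    parameters: report.RunParameters

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.config.fps


#: keypoint used as the contact proxy for each limb
_LIMB_PRIMARY = {"left_hand": "LWrist", "right_hand": "RWrist",
                 "left_foot": "LBigToe", "right_foot": "RBigToe"}
_LIMB_FALLBACK = {"left_foot": "LAnkle", "right_foot": "RAnkle"}


def _limb_track(series: kinematics.KeypointSeries, limb: str) -> np.ndarray:
    name = _LIMB_PRIMARY[limb]
    fallback = _LIMB_FALLBACK.get(limb)
    if fallback is not None:
        # prefer the toe only when it was actually observed most of the time
        if series.valid[name].mean() < 0.5 <= series.valid[fallback].mean():
            name = fallback
    return series.xy[name]


def _auto_side(pose_frames, image_width_px: float) -> str:
    votes = []
    for people in pose_frames:
        for p in people:
            valid = p[:, 2] > 0
            if valid.any():
                votes.append("left" if p[valid, 0].mean() < image_width_px / 2
                             else "right")
    if not votes:
        return "left"
    return "left" if votes.count("left") >= votes.count("right") else "right"


def analyze_run(pose_frames: Sequence, matches: Sequence[MatchPair],
                detections: Sequence[DetectionBox],
                route_map: Optional[RouteMap] = None,
                config: Optional[RunConfig] = None,
                table: Optional[AnthropometricTable] = None,
                side: Optional[str] = None) -> RunResult:
    """Run the full analysis on in-memory artifacts (native y-down pixels)."""
    cfg = config if config is not None else RunConfig()
    route_map = route_map if route_map is not None else load_route_map()
    table = table if table is not None else load_anthropometric_table()
    H = float(cfg.image_height_px)
    n = len(pose_frames)
    if n < 3:
        raise ValueError("need at least 3 pose frames")

    # --- skeleton: select athlete, flip to y-up, interpolate
    side = side if side is not None else _auto_side(pose_frames, cfg.image_width_px)
    skeletons = io_formats.select_athlete(list(pose_frames), side, cfg.image_width_px)
    if cfg.pixel_y_axis == "down":
        for sk in skeletons:
            sk.keypoints = {k: (x, H - y if c > 0 else y, c)
                            for k, (x, y, c) in sk.keypoints.items()}
    series = kinematics.frames_to_series(skeletons, cfg.min_confidence)
    series = kinematics.interpolate_missing(series)

    # --- camera motion (flip match endpoints to y-up)
    if cfg.pixel_y_axis == "down":
        matches = [replace(m, p_prev=(m.p_prev[0], H - m.p_prev[1]),
                           p_curr=(m.p_curr[0], H - m.p_curr[1]))
                   for m in matches]
    gamma = camera_motion.estimate_shift(
        matches, n, tol_px=cfg.vertical_match_tol_px, mad_k=cfg.mad_k)

    # --- holds and scale
    if cfg.pixel_y_axis == "down":
        detections = [replace(d, cy_px=H - d.cy_px) for d in detections]
    tracks = scal.track_and_identify_holds(detections, gamma, route_map)
    s_meas = scal.measure_scale_samples(tracks, route_map, n)
    scale = scal.fit_scale_model(s_meas, gamma)

    # --- COG kinematics: smooth the pixel track, then differentiate
    cog_px = kinematics.cog_track(series, table)
    anchor = _world_anchor(tracks, route_map)
    cog = kinematics.cog_series(cog_px, gamma, scale.s_fit, cfg.fps, anchor=anchor)
    cutoff = (kinematics.auto_cutoff(cog.v_ms, cfg.fps)
              if cfg.lowpass_cutoff_hz == "auto" else float(cfg.lowpass_cutoff_hz))
    cog_filt = kinematics.lowpass(cog_px, cutoff, cfg.fps)
    v_filt = kinematics.velocity(cog_filt, gamma, scale.s_fit, cfg.fps)
    cog_speed_filt = np.linalg.norm(v_filt, axis=1)

    # --- joint angles
    angles = {name: kinematics.joint_angle_series(series, name)
              for name in kinematics.JOINT_DEFS}
    angles["shoulder_hip"] = kinematics.trunk_inclination_series(series)

    # --- limb speeds and contacts
    radius = cfg.contact_radius_px
    contacts: List[contact_detection.ContactInterval] = []
    limb_speed_filt: Dict[str, np.ndarray] = {}
    for limb in _LIMB_PRIMARY:
        track = _limb_track(series, limb)
        track_filt = kinematics.lowpass(track, cutoff, cfg.fps)
        v = kinematics.velocity(track_filt, gamma, scale.s_fit, cfg.fps)
        speed = np.linalg.norm(v, axis=1)
        limb_speed_filt[limb] = speed
        ivs = contact_detection.contacts_from_speed(
            limb, speed, cfg.fps, eps=cfg.contact_speed_eps)
        contacts.extend(contact_detection.assign_contact_holds(
            ivs, track, tracks, gamma.cumulative_px,
            radius_px=radius, fps=cfg.fps))

    top = max(h.id for h in route_map.hand_holds())
    parameters = report.compute_parameters(
        cog_speed_filt, contacts, angles["shoulder_hip"].theta_deg, cfg.fps,
        top_hold=top)

    return RunResult(config=cfg, n_frames=n, skeleton=series, gamma=gamma,
                     tracks=tracks, scale=scale, cog=cog,
                     cog_speed_filt=cog_speed_filt, cutoff_hz=float(cutoff),
                     angles=angles, limb_speed_filt=limb_speed_filt,
                     contacts=contacts, parameters=parameters)


def _world_anchor(tracks: Sequence[scal.HoldTrack], route_map: RouteMap):
    """(frame, pixel, world) of the earliest identified hold sighting."""
    best = None
    for t in tracks:
        if t.map_id is None:
            continue
        if best is None or t.first_seen < best.first_seen:
            best = t
    if best is None:
        return None
    h = route_map.hold(best.map_id, best.kind)
    return (best.first_seen, best.centers_px[0], (h.x_m, h.y_m))


def analyze_files(pose_path, matches_path, detections_path,
                  route_map_path=None, config: Optional[RunConfig] = None,
                  side: Optional[str] = None) -> RunResult:
    """File-based entry point (paths as produced by ``speedkin synth``)."""
    pose = io_formats.read_pose_sequence(pose_path)
    matches = io_formats.read_matches(matches_path)
    detections = io_formats.read_detections(detections_path)
    route_map = load_route_map(route_map_path)
    return analyze_run(pose, matches, detections, route_map=route_map,
                       config=config, side=side)


# ---------------------------------------------------------------------------
# export

def result_tables(res: RunResult) -> Dict[str, pd.DataFrame]:
    """Flatten a RunResult into the exported CSV tables."""
    n, fps = res.n_frames, res.config.fps
    t = res.t_s

    def pad(v: np.ndarray) -> np.ndarray:
        return np.concatenate([v, [np.nan] * (n - len(v))])

    cog = pd.DataFrame({
        "frame": np.arange(n), "t_s": t,
        "x_px": res.cog.c_px[:, 0], "y_px": res.cog.c_px[:, 1],
        "x_m": res.cog.c_m[:, 0] if res.cog.c_m is not None else np.nan,
        "y_m": res.cog.c_m[:, 1] if res.cog.c_m is not None else np.nan,
        "vx_ms": pad(res.cog.v_ms[:, 0]), "vy_ms": pad(res.cog.v_ms[:, 1]),
        "speed_ms": pad(res.cog.speed_ms),
        "speed_filt_ms": pad(res.cog_speed_filt),
    })
    angles = pd.DataFrame({"frame": np.arange(n), "t_s": t})
    for name, ser in res.angles.items():
        angles[f"{name}_deg"] = ser.theta_deg
        angles[f"{name}_interpolated"] = ser.interpolated_mask.astype(int)
    contacts = pd.DataFrame(
        [{"limb": c.limb, "hold_kind": c.hold_kind,
          "hold_id": np.nan if c.hold_id is None else c.hold_id,
          "t_touch_s": c.t_touch, "t_release_s": c.t_release,
          "duration_s": c.duration,
          "sub_eps_start_s": np.nan if c.sub_eps_start is None else c.sub_eps_start,
          "sub_eps_end_s": np.nan if c.sub_eps_end is None else c.sub_eps_end}
         for c in res.contacts],
        columns=["limb", "hold_kind", "hold_id", "t_touch_s", "t_release_s",
                 "duration_s", "sub_eps_start_s", "sub_eps_end_s"])
    camera = pd.DataFrame({
        "frame": np.arange(n), "t_s": t,
        "gamma_px": pad(res.gamma.gamma_px),
        "cumulative_px": res.gamma.cumulative_px,
        "n_inliers": pad(res.gamma.n_inliers.astype(float)),
    })
    meas = dict(res.scale.s_meas)
    scale = pd.DataFrame({
        "frame": np.arange(n), "t_s": t,
        "alpha_rad": res.scale.alpha, "s_fit": res.scale.s_fit,
        "s_meas": [meas.get(f, np.nan) for f in range(n)],
    })
    return {"cog": cog, "angles": angles, "contacts": contacts,
            "camera": camera, "scale": scale,
            "parameters": res.parameters.to_frame()}


def export_result(res: RunResult, out_dir) -> Dict[str, object]:
    tables = result_tables(res)
    summary = {
        "n_frames": res.n_frames,
        "fps": res.config.fps,
        "cutoff_hz": res.cutoff_hz,
        "scale_A_px_per_m": res.scale.A,
        "scale_B_px": res.scale.B,
        "scale_alpha0_rad": res.scale.alpha0,
        "scale_fit_rmse": res.scale.residual,
        "n_hold_tracks": len(res.tracks),
        "n_contacts": len(res.contacts),
        "endtime_s": res.parameters.endtime_s,
    }
    return io_formats.write_report(out_dir, summary=summary, **tables)
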