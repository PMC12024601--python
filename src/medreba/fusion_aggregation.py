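"""Occlusion-resistant multi-camera fusion, temporal averaging and the
end-to-end session assessment.

Fusion takes, per joint and per co-indexed instant, the maximum point across
cameras, so a 0 occlusion sentinel survives only when every camera lost the
joint.  Temporal aggregation averages the fused per-frame points (zeros
included), rounds half away from zero, then clamps to the minimum grade 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import EmptyInputError
from .joint_angles import (JointAngles, PostureFlags, SIDES,
                           extract_joint_angles)
from .landmark_io import PointsSeries, SyncSession
from .reba_core import (Adjustments, JOINT_FIELDS, RebaPoints, ScoreBreakdown,
                        grade_legs, grade_lower_arm, grade_neck, grade_trunk,
                        grade_upper_arm, grade_wrist, reba_total)
from .head_pose import (CameraIntrinsics, FaceModel, estimate_head_pose,
                        HeadPose)
from .landmark_io import FACE_POINT_COUNT

logger = logging.getLogger(__name__)

__all__ = ["SessionResult", "fuse_frame", "aggregate_series",
           "occlusion_rate", "grade_frame", "assess_session"]


@dataclass
class SessionResult:
    fused_series: PointsSeries
    averaged_points: RebaPoints
    breakdown: ScoreBreakdown
    occlusion_single: float
    occlusion_fused: float
    per_camera_occlusion: dict
    per_camera_series: dict


def fuse_frame(per_camera_points: Sequence[RebaPoints]) -> RebaPoints:
    """Per-joint maximum across 1-3 cameras; 0 loses to any positive value."""
    pts = list(per_camera_points)
    if not pts:
        raise EmptyInputError("fuse_frame requires at least one camera")
    for p in pts:
        p.validate(allow_sentinel=True)
    return RebaPoints(**{f: max(getattr(p, f) for p in pts)
                         for f in JOINT_FIELDS})


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def aggregate_series(frames: Sequence[RebaPoints]) -> RebaPoints:
    """Arithmetic mean per joint (zeros included), rounded half away from
    zero, clamped to the minimum grade 1."""
    frames = list(frames)
    if not frames:
        raise EmptyInputError("aggregate_series requires at least one frame")
    out = {}
    for f in JOINT_FIELDS:
        mean = sum(getattr(p, f) for p in frames) / len(frames)
        out[f] = max(1, _round_half_away(mean))
    return RebaPoints(**out)


def occlusion_rate(series: PointsSeries) -> float:
    """Fraction of zero cells over frames x six joints."""
    cells = [getattr(p, f) for p in series.frames for f in JOINT_FIELDS]
    return sum(1 for c in cells if c == 0) / len(cells)


def _worse_side(values: dict) -> Optional[float]:
    """Conservative side selection: the larger magnitude across visible
    sides; None when both sides are missing."""
    present = [v for v in values.values() if v is not None]
    if not present:
        return None
    return max(present, key=abs)


def grade_frame(angles: JointAngles,
                flags: Optional[PostureFlags] = None) -> RebaPoints:
    """Grade one camera's joint angles into REBA points (0 for missing)."""
    fl = flags or angles.flags
    # per-side grading, worse (higher) point across sides
    ua = [grade_upper_arm(angles.upper_arm[s], fl.shoulder_raised,
                          fl.arm_abducted, fl.arm_supported)
          for s in SIDES if angles.upper_arm[s] is not None]
    la = [grade_lower_arm(angles.lower_arm[s])
          for s in SIDES if angles.lower_arm[s] is not None]
    wr = [grade_wrist(angles.wrist[s], fl.wrist_deviated)
          for s in SIDES if angles.wrist[s] is not None]
    lg = [grade_legs(angles.knee_flexion[s], fl.unilateral_stance)
          for s in SIDES if angles.knee_flexion[s] is not None]
    return RebaPoints(
        neck=grade_neck(angles.neck, fl.neck_twist_or_side_bend),
        trunk=grade_trunk(angles.trunk_flexion, fl.trunk_twist_or_side_bend),
        legs=max(lg) if lg else 0,
        upper_arm=max(ua) if ua else 0,
        lower_arm=max(la) if la else 0,
        wrist=max(wr) if wr else 0,
    )


def _head_pose_for(face_frame, resolution) -> Optional[HeadPose]:
    ids = FaceModel().landmark_ids
    if len(face_frame.points) != FACE_POINT_COUNT:
        return None
    w, h = resolution
    pts = [face_frame.points[i] for i in ids]
    if any(p.visibility < 0.5 for p in pts):
        return None
    obs = [(p.x * w, p.y * h) for p in pts]
    try:
        return estimate_head_pose(obs, FaceModel(),
                                  CameraIntrinsics.default_for(w, h))
    except Exception as exc:  # degenerate or non-convergent geometry
        logger.warning("head pose estimation failed: %s", exc)
        return None


def assess_session(session: SyncSession, *, adjustments=Adjustments(),
                   flags=PostureFlags(),
                   visibility_threshold: float = 0.5,
                   neck_reference: str = "absolute") -> SessionResult:
    """Full pipeline: per-camera grading of every aligned frame, per-instant
    fusion, temporal aggregation, chart scoring and risk banding."""
    if session.aligned_length < 1:
        raise EmptyInputError("session has no aligned frames")

    per_camera: dict[str, list] = {s.camera_label: [] for s in session.streams}
    fused = []
    for i in range(session.aligned_length):
        instant = []
        for stream in session.streams:
            frame = stream.frames[i]
            head = None
            face_stream = session.face_streams.get(stream.camera_label)
            if face_stream is not None and i < len(face_stream.frames):
                head = _head_pose_for(face_stream.frames[i],
                                      stream.resolution)
            w, h = stream.resolution
            angles = extract_joint_angles(
                frame, head, visibility_threshold, flags, neck_reference,
                aspect_ratio=w / h)
            pts = grade_frame(angles, flags)
            per_camera[stream.camera_label].append(pts)
            instant.append(pts)
        fused.append(fuse_frame(instant))

    fused_series = PointsSeries(camera_label="fused", frames=fused)
    averaged = aggregate_series(fused)
    lost = [f for f in JOINT_FIELDS
            if all(getattr(p, f) == 0 for p in fused)]
    if lost:
        logger.warning("joints %s occluded in every camera and frame; "
                       "clamped to minimum grade 1", lost)
    breakdown = reba_total(averaged, adjustments)

    cam_rates = {label: occlusion_rate(PointsSeries(label, frames))
                 for label, frames in per_camera.items()}
    return SessionResult(
        fused_series=fused_series,
        averaged_points=averaged,
        breakdown=breakdown,
        occlusion_single=sum(cam_rates.values()) / len(cam_rates),
        occlusion_fused=occlusion_rate(fused_series),
        per_camera_occlusion=cam_rates,
        per_camera_series={label: PointsSeries(label, frames)
                           for label, frames in per_camera.items()},
    )
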