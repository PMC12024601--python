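"""Joint-angle descriptors from a 33-point body frame.

All angles are measured in the 2-D image plane of each camera (each camera's
view is graded independently and the per-joint points fused downstream); the
landmark z channel is ignored for geometry.

Conventions (declared, degrees):

* trunk flexion      - mid-hip -> mid-shoulder segment vs image vertical-up;
                       0 upright, positive = lean magnitude.
* upper arm          - shoulder -> elbow vs the trunk-down line
                       (mid-shoulder -> mid-hip); falls back to image
                       vertical-down if the trunk landmarks are invisible.
* lower arm          - interior elbow angle (shoulder, elbow, wrist).
* wrist              - 180 deg minus the interior angle at the wrist
                       (elbow, wrist, index fingertip).
* knee flexion       - 180 deg minus the interior knee angle
                       (hip, knee, ankle); thigh reference falls back to
                       vertical-down if the hip is invisible.

A joint whose required landmarks fall below the visibility threshold is
marked missing (None) and later rendered as the 0 occlusion sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DegenerateGeometryError
from .landmark_io import BODY_LANDMARKS, LandmarkFrame
from .head_pose import HeadPose, neck_angle

__all__ = ["PostureFlags", "JointAngles", "angle_at", "trunk_flexion",
           "extract_joint_angles", "DEFAULT_VISIBILITY_THRESHOLD"]

DEFAULT_VISIBILITY_THRESHOLD = 0.5

#: Minimum fraction of a limb segment's length that must lie in the image
#: plane (cos 45 deg) for its projected angle to be trusted; segments more
#: oblique than that are treated like occlusions.  Set to 0 to disable
#: (e.g. when the z channel is absent).
DEFAULT_MIN_IN_PLANE = math.cos(math.radians(45.0))

SIDES = ("left", "right")


@dataclass(frozen=True)
class PostureFlags:
    """Grading modifiers that cannot be inferred from the landmark set;
    asserted per session via configuration, all false by default."""

    neck_twist_or_side_bend: bool = False
    trunk_twist_or_side_bend: bool = False
    shoulder_raised: bool = False
    arm_abducted: bool = False
    arm_supported: bool = False
    wrist_deviated: bool = False
    unilateral_stance: bool = False


@dataclass
class JointAngles:
    """Per-joint descriptors; None marks a joint with occluded landmarks.
    Per-side joints are keyed 'left'/'right'."""

    neck: Optional[float] = None
    trunk_flexion: Optional[float] = None
    upper_arm: dict = field(default_factory=lambda: {s: None for s in SIDES})
    lower_arm: dict = field(default_factory=lambda: {s: None for s in SIDES})
    wrist: dict = field(default_factory=lambda: {s: None for s in SIDES})
    knee_flexion: dict = field(default_factory=lambda: {s: None for s in SIDES})
    flags: PostureFlags = field(default_factory=PostureFlags)

    @property
    def missing(self) -> set:
        out = set()
        if self.neck is None:
            out.add("neck")
        if self.trunk_flexion is None:
            out.add("trunk")
        for joint in ("upper_arm", "lower_arm", "wrist", "knee_flexion"):
            vals = getattr(self, joint)
            if all(vals[s] is None for s in SIDES):
                out.add(joint)
        return out


def angle_at(a, b, c) -> float:
    """Interior angle at b (degrees, in [0, 180]) for 2-D or 3-D points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("zero-length limb vector at the vertex")
    if u.shape[-1] == 2:
        cross = abs(u[0] * v[1] - u[1] * v[0])
    else:
        cross = np.linalg.norm(np.cross(u, v))
    return math.degrees(math.atan2(cross, float(u @ v)))


def _vec_angle(u, v) -> float:
    """Unsigned angle between two 2-D vectors, degrees."""
    cross = abs(u[0] * v[1] - u[1] * v[0])
    return math.degrees(math.atan2(cross, float(u @ v)))


class _Frame:
    """Visibility-gated accessor over a body frame's 2-D coordinates.

    Normalized landmarks are anisotropic (x over width, y over height), so x
    is re-scaled by the image aspect ratio before any angle geometry.  The z
    channel (height-normalized relative depth, same scale as the corrected
    image coordinates) is used only to gate segments that tilt too far out
    of the image plane - their projected angles are meaningless.
    """

    def __init__(self, frame: LandmarkFrame, threshold: float,
                 aspect_ratio: float = 1.0,
                 min_in_plane: float = DEFAULT_MIN_IN_PLANE):
        self.frame = frame
        self.threshold = threshold
        self.aspect = aspect_ratio
        self.min_in_plane = min_in_plane

    def visible(self, *names: str) -> bool:
        return all(self.frame.points[BODY_LANDMARKS[n]].visibility
                   >= self.threshold for n in names)

    def xy(self, name: str) -> np.ndarray:
        p = self.frame.points[BODY_LANDMARKS[name]]
        return np.array([p.x * self.aspect, p.y])

    def _xyz(self, name: str) -> np.ndarray:
        p = self.frame.points[BODY_LANDMARKS[name]]
        return np.array([p.x * self.aspect, p.y, p.z])

    def _seg(self, a, b) -> np.ndarray:
        pa = np.mean([self._xyz(n)
                      for n in (a if isinstance(a, tuple) else (a,))], axis=0)
        pb = np.mean([self._xyz(n)
                      for n in (b if isinstance(b, tuple) else (b,))], axis=0)
        return pb - pa

    def in_plane(self, *segments) -> bool:
        """True when every (start, end) landmark-name segment keeps at least
        ``min_in_plane`` of its length in the image plane."""
        for a, b in segments:
            d = self._seg(a, b)
            full = np.linalg.norm(d)
            if full < 1e-12:
                continue
            if np.linalg.norm(d[:2]) / full < self.min_in_plane:
                return False
        return True

    def bend_ok(self, a, b, c) -> bool:
        """Gate for a three-point interior angle at b: trustworthy when the
        bend plane is fronto-parallel (its normal points along the optical
        axis) or the limb is near-straight (collinearity survives any
        projection)."""
        d1 = self._seg(b, a)
        d2 = self._seg(b, c)
        n = np.cross(d1, d2)
        nn = np.linalg.norm(n)
        straight = 0.2 * np.linalg.norm(d1) * np.linalg.norm(d2)
        if nn < straight:
            return True
        return abs(n[2]) / nn >= self.min_in_plane


_UP = np.array([0.0, -1.0])     # image y grows downward
_DOWN = np.array([0.0, 1.0])


_TRUNK_SEG = ((("left_hip", "right_hip"), ("left_shoulder", "right_shoulder")),)


def trunk_flexion(frame: LandmarkFrame,
                  visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
                  aspect_ratio: float = 1.0,
                  min_in_plane: float = DEFAULT_MIN_IN_PLANE
                  ) -> Optional[float]:
    """Lean of the mid-hip -> mid-shoulder segment from vertical; None when
    the hips or shoulders are below the visibility threshold or the trunk
    is too foreshortened in this view."""
    f = _Frame(frame, visibility_threshold, aspect_ratio, min_in_plane)
    if not f.visible("left_shoulder", "right_shoulder",
                     "left_hip", "right_hip"):
        return None
    if not f.in_plane(*_TRUNK_SEG):
        return None
    mid_sh = (f.xy("left_shoulder") + f.xy("right_shoulder")) / 2.0
    mid_hip = (f.xy("left_hip") + f.xy("right_hip")) / 2.0
    v = mid_sh - mid_hip
    if np.linalg.norm(v) < 1e-12:
        raise DegenerateGeometryError("coincident mid-hip and mid-shoulder")
    return _vec_angle(v, _UP)


def extract_joint_angles(body: LandmarkFrame, head: Optional[HeadPose] = None,
                         visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
                         flags: PostureFlags = PostureFlags(),
                         neck_reference: str = "absolute",
                         aspect_ratio: float = 1.0,
                         min_in_plane: float = DEFAULT_MIN_IN_PLANE
                         ) -> JointAngles:
    """Compute all joint descriptors for one body frame.

    ``head`` supplies the neck angle via the face chain; without it the neck
    is marked missing.  ``aspect_ratio`` (width/height) undoes the
    anisotropy of normalized landmark coordinates.  Segments tilted beyond
    the ``min_in_plane`` gate (see DEFAULT_MIN_IN_PLANE) render their joints
    missing in this view, exactly like occluded landmarks.
    """
    f = _Frame(body, visibility_threshold, aspect_ratio, min_in_plane)
    out = JointAngles(flags=flags)

    trunk = trunk_flexion(body, visibility_threshold, aspect_ratio,
                          min_in_plane)
    out.trunk_flexion = trunk

    trunk_landmarks_visible = f.visible("left_shoulder", "right_shoulder",
                                        "left_hip", "right_hip")
    # trunk visible but too foreshortened: its line cannot serve as the
    # upper-arm reference either, so the upper arm is gated with it
    trunk_gated = trunk_landmarks_visible and trunk is None
    if trunk is not None:
        mid_sh = (f.xy("left_shoulder") + f.xy("right_shoulder")) / 2.0
        mid_hip = (f.xy("left_hip") + f.xy("right_hip")) / 2.0
        trunk_down = mid_hip - mid_sh
    else:
        trunk_down = _DOWN

    if head is not None:
        out.neck = neck_angle(head, trunk or 0.0, neck_reference)

    for side in SIDES:
        sh, el, wr, ix = (f"{side}_shoulder", f"{side}_elbow",
                          f"{side}_wrist", f"{side}_index")
        hip, knee, ankle = f"{side}_hip", f"{side}_knee", f"{side}_ankle"

        if f.visible(sh, el) and f.in_plane((sh, el)) and not trunk_gated:
            out.upper_arm[side] = _vec_angle(f.xy(el) - f.xy(sh), trunk_down)
        if f.visible(sh, el, wr) and f.in_plane((sh, el), (el, wr)) \
                and f.bend_ok(sh, el, wr):
            out.lower_arm[side] = angle_at(f.xy(sh), f.xy(el), f.xy(wr))
        if f.visible(el, wr, ix) and f.in_plane((el, wr), (wr, ix)) \
                and f.bend_ok(el, wr, ix):
            out.wrist[side] = 180.0 - angle_at(f.xy(el), f.xy(wr), f.xy(ix))
        if f.visible(knee, ankle) and f.in_plane((knee, ankle)):
            use_hip = f.visible(hip) and f.in_plane((hip, knee))
            if use_hip and not f.bend_ok(hip, knee, ankle):
                continue
            thigh_down = (f.xy(knee) - f.xy(hip)) if use_hip else _DOWN
            out.knee_flexion[side] = _vec_angle(f.xy(ankle) - f.xy(knee),
                                                thigh_down)
    return out
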