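"""REBA grading: angle-to-point graders, the worksheet lookup tables, score
assembly with load/coupling/activity adjustments, and risk banding.

Point vocabulary
----------------
*Points* are per-joint grades (neck 1-3, trunk 1-5, legs 1-4, upper arm 1-6,
lower arm 1-2, wrist 1-3); the value 0 is an occlusion sentinel, never a valid
grade.  The *score* is the chart-combined 1-15 total: Table A (neck, trunk,
legs) + load -> Score A; Table B (upper arm, lower arm, wrist) + coupling ->
Score B; Table C(A, B) -> Score C; total = Score C + activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .errors import BoundsError, SentinelError

__all__ = [
    "RebaPoints",
    "Adjustments",
    "ScoreBreakdown",
    "POINT_BOUNDS",
    "grade_neck",
    "grade_trunk",
    "grade_legs",
    "grade_upper_arm",
    "grade_lower_arm",
    "grade_wrist",
    "table_a",
    "table_b",
    "table_c",
    "reba_total",
    "classify_risk",
    "RISK_BANDS",
]

#: Valid (inclusive) grade range per joint, excluding the 0 sentinel.
POINT_BOUNDS = {
    "neck": (1, 3),
    "trunk": (1, 5),
    "legs": (1, 4),
    "upper_arm": (1, 6),
    "lower_arm": (1, 2),
    "wrist": (1, 3),
}

JOINT_FIELDS = tuple(POINT_BOUNDS)


@dataclass(frozen=True)
class RebaPoints:
    """Per-joint REBA points; 0 marks an occluded (unobservable) joint."""

    neck: int = 0
    trunk: int = 0
    legs: int = 0
    upper_arm: int = 0
    lower_arm: int = 0
    wrist: int = 0

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.neck, self.trunk, self.legs,
                self.upper_arm, self.lower_arm, self.wrist)

    def validate(self, allow_sentinel: bool = True) -> None:
        for name, (lo, hi) in POINT_BOUNDS.items():
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise BoundsError(f"{name} point must be an integer, got {v!r}")
            floor = 0 if allow_sentinel else lo
            if not floor <= v <= hi:
                raise BoundsError(
                    f"{name} point {v} outside [{floor}, {hi}]")

    def has_sentinel(self) -> bool:
        return 0 in self.as_tuple()

    def clamp_min_one(self) -> "RebaPoints":
        """Replace 0 sentinels by the minimum grade 1."""
        return replace(self, **{f: max(1, getattr(self, f)) for f in JOINT_FIELDS})


@dataclass(frozen=True)
class Adjustments:
    """Additive load (Score A), coupling (Score B) and activity modifiers."""

    load: int = 1
    coupling: int = 1
    activity: int = 1

    def validate(self) -> None:
        for name in ("load", "coupling", "activity"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 3:
                raise BoundsError(f"{name} adjustment {v!r} outside 0-3")


@dataclass(frozen=True)
class ScoreBreakdown:
    score_a: int
    score_b: int
    score_c: int
    total: int
    band: str


# ---------------------------------------------------------------------------
# Angle -> point graders.  A missing angle (None or NaN) grades to the 0
# sentinel.  Band boundaries are inclusive at the lower grade.
# ---------------------------------------------------------------------------

def _missing(angle: Optional[float]) -> bool:
    return angle is None or (isinstance(angle, float) and math.isnan(angle))


def grade_neck(angle: Optional[float], twist_or_side: bool = False) -> int:
    """Neck point: 1 for 0-20 deg flexion, 2 beyond 20 deg or any extension
    (negative angle); +1 for twist/side-bend, capped at 3."""
    if _missing(angle):
        return 0
    point = 1 if 0.0 <= angle <= 20.0 else 2
    if twist_or_side:
        point += 1
    return min(point, 3)


def grade_trunk(angle: Optional[float], twist_or_side: bool = False,
                upright_tol: float = 3.0) -> int:
    """Trunk point from signed flexion (extension negative).

    upright (within upright_tol) 1; <=20 deg flexion or extension 2; 20-60 flexion or >20
    extension 3; >60 flexion 4; +1 twist/side-bend, capped at 5.
    """
    if _missing(angle):
        return 0
    mag = abs(angle)
    if mag <= upright_tol:
        point = 1
    elif mag <= 20.0:
        point = 2
    elif angle > 60.0:
        point = 4
    else:  # 20-60 flexion, or any extension beyond 20
        point = 3
    if twist_or_side:
        point += 1
    return min(point, 5)


def grade_legs(knee_flexion: Optional[float], unilateral: bool = False) -> int:
    """Leg point: bilateral stance 1 / unilateral 2; +1 for knee flexion
    30-60 deg, +2 beyond 60 deg; capped at 4."""
    if _missing(knee_flexion):
        return 0
    point = 2 if unilateral else 1
    if knee_flexion > 60.0:
        point += 2
    elif knee_flexion > 30.0:
        point += 1
    return min(point, 4)


def grade_upper_arm(angle: Optional[float], shoulder_raised: bool = False,
                    abducted: bool = False, supported: bool = False) -> int:
    """Upper-arm point from signed flexion (extension negative).

    -20..20 -> 1; 20-45 flexion or >20 extension -> 2; 45-90 -> 3; >90 -> 4;
    +1 raised shoulder, +1 abduction, -1 supported; clamped to 1-6.
    """
    if _missing(angle):
        return 0
    mag = abs(angle)
    if mag <= 20.0:
        point = 1
    elif angle > 90.0:
        point = 4
    elif angle > 45.0:
        point = 3
    else:
        point = 2
    point += int(shoulder_raised) + int(abducted) - int(supported)
    return min(max(point, 1), 6)


def grade_lower_arm(angle: Optional[float]) -> int:
    """Lower-arm point: elbow interior flexion 60-100 deg -> 1, else 2."""
    if _missing(angle):
        return 0
    return 1 if 60.0 <= angle <= 100.0 else 2


def grade_wrist(angle: Optional[float], deviated: bool = False) -> int:
    """Wrist point: within +/-15 deg -> 1, else 2; +1 deviation/twist, cap 3."""
    if _missing(angle):
        return 0
    point = 1 if abs(angle) <= 15.0 else 2
    if deviated:
        point += 1
    return min(point, 3)


# ---------------------------------------------------------------------------
# Worksheet tables, embedded verbatim.  Indexing is [point - 1].
# ---------------------------------------------------------------------------

# TABLE_A[neck-1][trunk-1][legs-1]
TABLE_A = (
    (  # neck 1
        (1, 2, 3, 4), (2, 3, 4, 5), (2, 4, 5, 6), (3, 5, 6, 7), (4, 6, 7, 8),
    ),
    (  # neck 2
        (1, 2, 3, 4), (3, 4, 5, 6), (4, 5, 6, 7), (5, 6, 7, 8), (6, 7, 8, 9),
    ),
    (  # neck 3
        (3, 3, 5, 6), (4, 5, 6, 7), (5, 6, 7, 8), (6, 7, 8, 9), (7, 8, 9, 9),
    ),
)

# TABLE_B[upper_arm-1][lower_arm-1][wrist-1]
TABLE_B = (
    ((1, 2, 2), (1, 2, 3)),
    ((1, 2, 3), (2, 3, 4)),
    ((3, 4, 5), (4, 5, 5)),
    ((4, 5, 5), (5, 6, 7)),
    ((6, 7, 8), (7, 8, 8)),
    ((7, 8, 8), (8, 9, 9)),
)

# TABLE_C[score_a-1][score_b-1]
TABLE_C = (
    (1, 1, 1, 2, 3, 3, 4, 5, 6, 7, 7, 7),
    (1, 2, 2, 3, 4, 4, 5, 6, 6, 7, 7, 8),
    (2, 3, 3, 3, 4, 5, 6, 7, 7, 8, 8, 8),
    (3, 4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9),
    (4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9, 9),
    (6, 6, 6, 7, 8, 8, 9, 9, 10, 10, 10, 10),
    (7, 7, 7, 8, 9, 9, 9, 10, 10, 11, 11, 11),
    (8, 8, 8, 9, 10, 10, 10, 10, 10, 11, 11, 11),
    (9, 9, 9, 10, 10, 10, 11, 11, 11, 12, 12, 12),
    (10, 10, 10, 11, 11, 11, 11, 12, 12, 12, 12, 12),
    (11, 11, 11, 11, 12, 12, 12, 12, 12, 12, 12, 12),
    (12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12),
)


def _check(name: str, value: int, lo: int, hi: int) -> None:
    if not isinstance(value, int) or isinstance(value, bool) or not lo <= value <= hi:
        raise BoundsError(f"{name} must be an integer in [{lo}, {hi}], got {value!r}")


def table_a(neck: int, trunk: int, legs: int) -> int:
    """Posture score from neck, trunk and leg points (1-9)."""
    _check("neck", neck, 1, 3)
    _check("trunk", trunk, 1, 5)
    _check("legs", legs, 1, 4)
    return TABLE_A[neck - 1][trunk - 1][legs - 1]


def table_b(upper_arm: int, lower_arm: int, wrist: int) -> int:
    """Posture score from upper-arm, lower-arm and wrist points (1-9)."""
    _check("upper_arm", upper_arm, 1, 6)
    _check("lower_arm", lower_arm, 1, 2)
    _check("wrist", wrist, 1, 3)
    return TABLE_B[upper_arm - 1][lower_arm - 1][wrist - 1]


def table_c(score_a: int, score_b: int) -> int:
    """Combined Score C from Score A and Score B (1-12)."""
    _check("score_a", score_a, 1, 12)
    _check("score_b", score_b, 1, 12)
    return TABLE_C[score_a - 1][score_b - 1]


def reba_total(points: RebaPoints, adj: Adjustments = Adjustments()) -> ScoreBreakdown:
    """Assemble the full REBA score from six valid joint points.

    Raises SentinelError if any joint still carries the 0 sentinel: fuse
    across cameras or clamp (``RebaPoints.clamp_min_one``) first.
    """
    if points.has_sentinel():
        raise SentinelError(
            "occlusion sentinel 0 present; fuse cameras or clamp to 1 "
            "before scoring")
    points.validate(allow_sentinel=False)
    adj.validate()
    score_a = min(table_a(points.neck, points.trunk, points.legs) + adj.load, 12)
    score_b = min(table_b(points.upper_arm, points.lower_arm, points.wrist)
                  + adj.coupling, 12)
    score_c = table_c(score_a, score_b)
    total = min(score_c + adj.activity, 15)
    return ScoreBreakdown(score_a=score_a, score_b=score_b, score_c=score_c,
                          total=total, band=classify_risk(total))


#: Risk bands as (low, high, label), inclusive.
RISK_BANDS = (
    (1, 1, "negligible"),
    (2, 3, "low"),
    (4, 7, "medium"),
    (8, 10, "high"),
    (11, 15, "very_high"),
)


def classify_risk(total: int) -> str:
    """Map a 1-15 REBA total to its risk band."""
    _check("total", total, 1, 15)
    for lo, hi, label in RISK_BANDS:
        if lo <= total <= hi:
            return label
    raise BoundsError(f"total {total} outside 1-15")  # pragma: no cover
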