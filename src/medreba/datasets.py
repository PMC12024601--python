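"""Bundled reference data: the 18-subject dentist cohort point table, the
single-instant three-camera comparison, two six-frame point series (one
fully observed, one occlusion-laden), the reference linear score model, and
the optimization verification profiles.  These small tables drive the
regression tests and the acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .landmark_io import PointsSeries
from .reba_core import RebaPoints

__all__ = [
    "CAMERA_INSTANT", "FRAME_SERIES", "OCCLUDED_SERIES",
    "DENTIST_COHORT", "SEATED_IDS", "STANDING_IDS",
    "REFERENCE_MODEL_COEFFS", "OPTIMIZATION_VERIFICATION",
    "camera_instant_series", "frame_series", "occluded_series",
]


@dataclass(frozen=True)
class CohortEntry:
    """One subject's per-joint REBA points and reported total."""

    subject: int
    points: RebaPoints
    reba: int


def _p(n, t, lg, ua, la, w):
    return RebaPoints(neck=n, trunk=t, legs=lg, upper_arm=ua,
                      lower_arm=la, wrist=w)


#: Three cameras' points at one instant (0 = occluded joint in that view).
CAMERA_INSTANT = {
    "C1": _p(3, 0, 0, 2, 2, 3),
    "C2": _p(1, 1, 1, 1, 1, 1),
    "C3": _p(3, 3, 1, 3, 2, 3),
}

#: Six consecutive fully-observed frames of a single fused stream; the
#: reported per-joint average row is (2, 2, 1, 3, 2, 1).
FRAME_SERIES = [
    _p(2, 2, 1, 3, 2, 1),
    _p(2, 2, 1, 5, 2, 2),
    _p(1, 2, 1, 2, 2, 1),
    _p(2, 2, 1, 4, 2, 1),
    _p(3, 2, 1, 1, 2, 1),
    _p(3, 2, 1, 3, 2, 2),
]

#: Six single-camera frames with occlusion sentinels (10 zero cells); the
#: reported average row after zero-included mean/round/clamp is
#: (1, 2, 1, 2, 2, 1).
OCCLUDED_SERIES = [
    _p(0, 2, 1, 0, 2, 0),
    _p(0, 0, 1, 5, 2, 2),
    _p(1, 2, 1, 0, 0, 0),
    _p(2, 2, 1, 3, 2, 0),
    _p(0, 2, 1, 1, 2, 1),
    _p(3, 2, 1, 3, 2, 1),
]

#: 18-subject cohort: (neck, trunk, legs, upper arm, lower arm, wrist, total).
_COHORT_ROWS = [
    (1, 2, 4, 1, 4, 1, 2, 9),
    (2, 2, 3, 1, 4, 1, 2, 8),
    (3, 3, 3, 1, 5, 1, 2, 10),
    (4, 2, 5, 1, 6, 1, 2, 12),
    (5, 2, 4, 1, 4, 1, 2, 9),
    (6, 2, 3, 1, 5, 2, 2, 10),
    (7, 2, 3, 1, 4, 1, 2, 8),
    (8, 2, 4, 1, 4, 1, 2, 9),
    (9, 2, 4, 1, 4, 2, 2, 10),
    (10, 3, 3, 1, 4, 1, 2, 9),
    (11, 3, 3, 1, 4, 2, 2, 10),
    (12, 2, 3, 1, 3, 2, 2, 8),
    (13, 3, 4, 3, 5, 1, 2, 12),
    (14, 2, 3, 2, 3, 2, 2, 9),
    (15, 2, 3, 1, 4, 1, 2, 8),
    (16, 3, 4, 3, 4, 1, 2, 12),
    (17, 2, 4, 1, 4, 2, 2, 10),
    (18, 3, 3, 2, 3, 1, 2, 10),
]

DENTIST_COHORT = [CohortEntry(r[0], _p(*r[1:7]), r[7]) for r in _COHORT_ROWS]

#: Four subjects worked standing (anomalous profiles); the rest were seated.
STANDING_IDS = (13, 14, 16, 18)
SEATED_IDS = tuple(e.subject for e in DENTIST_COHORT
                   if e.subject not in STANDING_IDS)

#: Reference linear score model over (neck, trunk, upper arm, lower arm):
#: intercept and coefficients.
REFERENCE_MODEL_COEFFS = {
    "intercept": -1.53635,
    "neck": 1.049,
    "trunk": 1.0,
    "upper_arm": 0.925148,
    "lower_arm": 0.865374,
}

#: Reported optimization solutions: continuous optimum, rounded chart-scored
#: verification levels (neck, trunk, upper arm, lower arm) and totals.
OPTIMIZATION_VERIFICATION = {
    "maximize": {"continuous": (2.98, 4.90, 4.05, 1.0),
                 "predicted": 11.11,
                 "rounded": (3, 5, 4, 1),
                 "verification_total": 11,
                 "desirability": 1.0},
    "minimize": {"continuous": (2.0, 3.0, 3.0, 1.0),
                 "predicted": 7.2,
                 "rounded": (2, 3, 3, 1),
                 "verification_total": 7,
                 "desirability": 0.95},
}


def camera_instant_series() -> list:
    """The three-camera instant as three one-frame PointsSeries."""
    return [PointsSeries(camera_label=label, frames=[pts])
            for label, pts in CAMERA_INSTANT.items()]


def frame_series() -> PointsSeries:
    return PointsSeries(camera_label="fused", frames=list(FRAME_SERIES))


def occluded_series() -> PointsSeries:
    return PointsSeries(camera_label="C1", frames=list(OCCLUDED_SERIES))
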