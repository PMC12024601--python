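"""Head-pose estimation from six face landmarks.

A rigid six-point canonical face template is fitted to the observed image
points by perspective-n-point: a weak-perspective (scaled-orthographic
Procrustes) initialization followed by Levenberg-Marquardt reprojection
refinement.  The recovered rotation is decomposed into intrinsic x-y-z Euler
angles (pitch about the lateral axis, then yaw, then roll); pitch feeds the
neck grader, with positive pitch meaning head flexion (looking down).

Camera convention: x right, y down, z forward (into the scene); image origin
top-left.  All angles in degrees unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, EstimationError, ProjectionError

__all__ = [
    "FACE_LANDMARK_IDS", "CANONICAL_FACE_POINTS", "FaceModel",
    "CameraIntrinsics", "HeadPose",
    "rodrigues_to_matrix", "matrix_to_rodrigues",
    "euler_from_matrix", "euler_to_matrix",
    "project_points", "estimate_head_pose", "neck_angle",
]

#: Face-mesh indices of the six pose landmarks (nose tip, eye outer corners,
#: mouth corners, chin).
FACE_LANDMARK_IDS = (1, 33, 263, 61, 291, 199)

#: Canonical 3-D template for the six landmarks, unitless scale, nose tip at
#: the origin, y down, z away from the camera at neutral pose.
CANONICAL_FACE_POINTS = np.array([
    [0.000,  0.000, 0.000],   # 1   nose tip
    [-0.225, -0.170, 0.135],  # 33  eye outer corner (image left)
    [0.225, -0.170, 0.135],   # 263 eye outer corner (image right)
    [-0.150,  0.150, 0.125],  # 61  mouth corner (image left)
    [0.150,  0.150, 0.125],   # 291 mouth corner (image right)
    [0.000,  0.330, 0.065],   # 199 chin
])


@dataclass(frozen=True)
class FaceModel:
    landmark_ids: tuple = FACE_LANDMARK_IDS
    model_points: np.ndarray = field(
        default_factory=lambda: CANONICAL_FACE_POINTS.copy())

    def __post_init__(self) -> None:
        pts = np.asarray(self.model_points, dtype=float)
        if pts.shape != (6, 3):
            raise DegenerateGeometryError("face model requires six 3-D points")
        if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
            raise DegenerateGeometryError("face model points are collinear")


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: single focal length in pixels, principal point,
    Brown distortion coefficients (k1, k2, p1, p2, k3)."""

    focal: float
    principal_point: tuple[float, float]
    distortion: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.focal <= 0:
            raise DegenerateGeometryError(f"focal must be > 0, got {self.focal}")

    @classmethod
    def default_for(cls, width: int, height: int) -> "CameraIntrinsics":
        """Common head-pose heuristic: focal = image width, centered pp."""
        return cls(focal=float(width),
                   principal_point=(width / 2.0, height / 2.0))


@dataclass(frozen=True)
class HeadPose:
    rotation_vector: np.ndarray
    rotation_matrix: np.ndarray
    pitch: float
    yaw: float
    roll: float
    translation: np.ndarray = None
    reprojection_rms: float = 0.0
    gimbal_lock: bool = False


# ---------------------------------------------------------------------------
# Rotation plumbing
# ---------------------------------------------------------------------------

def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def rodrigues_to_matrix(rvec) -> np.ndarray:
    """Axis-angle (radians) to 3x3 rotation matrix."""
    v = np.asarray(rvec, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise DegenerateGeometryError("non-finite rotation vector")
    theta = float(np.linalg.norm(v))
    if theta < 1e-12:
        K = _skew(v)
        return np.eye(3) + K + 0.5 * (K @ K)
    k = _skew(v / theta)
    return np.eye(3) + math.sin(theta) * k + (1.0 - math.cos(theta)) * (k @ k)


def matrix_to_rodrigues(R) -> np.ndarray:
    """Rotation matrix to axis-angle with |angle| <= pi."""
    R = np.asarray(R, dtype=float)
    cos_t = max(-1.0, min(1.0, (np.trace(R) - 1.0) / 2.0))
    theta = math.acos(cos_t)
    if theta < 1e-8:
        return 0.5 * np.array([R[2, 1] - R[1, 2],
                               R[0, 2] - R[2, 0],
                               R[1, 0] - R[0, 1]])
    if math.pi - theta < 1e-6:
        # near 180 deg: axis from the symmetric part
        B = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.maximum(np.diag(B), 0.0))
        # fix signs from the largest component
        i = int(np.argmax(axis))
        if axis[i] > 0:
            for j in range(3):
                if j != i and B[i, j] < 0:
                    axis[j] = -axis[j]
        axis /= np.linalg.norm(axis)
        return theta * axis
    axis = np.array([R[2, 1] - R[1, 2],
                     R[0, 2] - R[2, 0],
                     R[1, 0] - R[0, 1]]) / (2.0 * math.sin(theta))
    return theta * axis


def _rx(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def euler_to_matrix(pitch: float, yaw: float, roll: float) -> np.ndarray:
    """Compose intrinsic x-y-z Euler angles (degrees) into a matrix."""
    return (_rx(math.radians(pitch)) @ _ry(math.radians(yaw))
            @ _rz(math.radians(roll)))


def euler_from_matrix(R) -> tuple[float, float, float, bool]:
    """Decompose under the intrinsic x-y-z order.

    Returns (pitch, yaw, roll, gimbal_lock) in degrees.  At gimbal lock
    (|cos(yaw)| ~ 0) roll is set to 0 by convention and the flag is raised.
    """
    R = np.asarray(R, dtype=float)
    if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-6:
        raise DegenerateGeometryError("matrix is not orthonormal")
    sy = max(-1.0, min(1.0, R[0, 2]))
    yaw = math.asin(sy)
    if abs(math.cos(yaw)) < 1e-9:
        # R reduces to a function of pitch+roll only; put it all in pitch
        pitch = math.atan2(R[1, 0], R[1, 1])
        return math.degrees(pitch), math.degrees(yaw), 0.0, True
    pitch = math.atan2(-R[1, 2], R[2, 2])
    roll = math.atan2(-R[0, 1], R[0, 0])
    return math.degrees(pitch), math.degrees(yaw), math.degrees(roll), False


# ---------------------------------------------------------------------------
# Projection and PnP
# ---------------------------------------------------------------------------

def project_points(points_3d, rvec, tvec, intrinsics: CameraIntrinsics,
                   _z_tol: float = 1e-9) -> np.ndarray:
    """Pinhole projection of world points under (rvec, tvec), with Brown
    distortion.  Raises ProjectionError for points at or behind the camera."""
    P = np.atleast_2d(np.asarray(points_3d, dtype=float))
    R = rodrigues_to_matrix(rvec)
    t = np.asarray(tvec, dtype=float).reshape(3)
    cam = P @ R.T + t
    if np.any(cam[:, 2] <= _z_tol):
        raise ProjectionError("point at or behind the camera plane (z <= 0)")
    x = cam[:, 0] / cam[:, 2]
    y = cam[:, 1] / cam[:, 2]
    k1, k2, p1, p2, k3 = (tuple(intrinsics.distortion) + (0.0,) * 5)[:5]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    cx, cy = intrinsics.principal_point
    f = intrinsics.focal
    return np.column_stack([f * xd + cx, f * yd + cy])


def _weak_perspective_init(model: np.ndarray, obs_norm: np.ndarray):
    """Scaled-orthographic Procrustes estimate of (R, t)."""
    Pc = model - model.mean(axis=0)
    uc = obs_norm - obs_norm.mean(axis=0)
    M, *_ = np.linalg.lstsq(Pc, uc, rcond=None)
    M = M.T  # 2x3 so that uc ~ Pc @ M.T
    n1, n2 = np.linalg.norm(M[0]), np.linalg.norm(M[1])
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("degenerate weak-perspective estimate")
    s = (n1 + n2) / 2.0
    r1 = M[0] / n1
    r2 = M[1] - (M[1] @ r1) * r1
    r2 /= np.linalg.norm(r2)
    r3 = np.cross(r1, r2)
    R0 = np.vstack([r1, r2, r3])
    # re-orthonormalize via SVD (Procrustes projection onto SO(3))
    U, _, Vt = np.linalg.svd(R0)
    R0 = U @ Vt
    if np.linalg.det(R0) < 0:
        U[:, -1] *= -1
        R0 = U @ Vt
    tz = 1.0 / s
    mean_cam = R0 @ model.mean(axis=0)
    t0 = np.array([obs_norm[:, 0].mean() * tz - mean_cam[0],
                   obs_norm[:, 1].mean() * tz - mean_cam[1],
                   tz - mean_cam[2]])
    return R0, t0


def estimate_head_pose(observed_2d, model: FaceModel,
                       intrinsics: CameraIntrinsics) -> HeadPose:
    """Recover head rotation (and translation) from six observed image points.

    Raises DegenerateGeometryError for collinear observations and
    EstimationError on optimizer failure.
    """
    obs = np.asarray(observed_2d, dtype=float)
    if obs.shape != (6, 2) or not np.all(np.isfinite(obs)):
        raise DegenerateGeometryError("expected six finite 2-D observations")
    centered = obs - obs.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] < 1e-9 or sv[1] / sv[0] < 1e-6:
        raise DegenerateGeometryError("observed points are collinear")

    cx, cy = intrinsics.principal_point
    obs_norm = (obs - (cx, cy)) / intrinsics.focal
    P = np.asarray(model.model_points, dtype=float)
    R0, t0 = _weak_perspective_init(P, obs_norm)
    if t0[2] <= 0:  # template behind the camera: flip depth
        t0 = np.array([t0[0], t0[1], abs(t0[2]) + 1.0])
    x0 = np.concatenate([matrix_to_rodrigues(R0), t0])

    def residual(x):
        cam = P @ rodrigues_to_matrix(x[:3]).T + x[3:]
        z = cam[:, 2]
        if np.any(z <= 1e-6):
            return np.full(12, 1e3)
        proj = cam[:, :2] / z[:, None]
        return (proj - obs_norm).ravel()

    sol = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14,
                        max_nfev=500)
    if not sol.success:
        raise EstimationError(
            f"PnP refinement failed after {sol.nfev} evaluations: "
            f"{sol.message}")
    rvec, tvec = sol.x[:3], sol.x[3:]
    R = rodrigues_to_matrix(rvec)
    rms = float(np.sqrt(np.mean(sol.fun ** 2))) * intrinsics.focal
    pitch, yaw, roll, lock = euler_from_matrix(R)
    return HeadPose(rotation_vector=rvec, rotation_matrix=R, pitch=pitch,
                    yaw=yaw, roll=roll, translation=tvec,
                    reprojection_rms=rms, gimbal_lock=lock)


def neck_angle(pose: HeadPose, trunk_flexion: float = 0.0,
               reference: str = "absolute") -> float:
    """Neck flexion in degrees.

    ``absolute`` returns camera-frame pitch; ``trunk_relative`` subtracts the
    trunk flexion (flexion positive for both).
    """
    if reference == "absolute":
        return pose.pitch
    if reference == "trunk_relative":
        return pose.pitch - trunk_flexion
    raise ValueError(f"unknown neck reference {reference!r}")
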