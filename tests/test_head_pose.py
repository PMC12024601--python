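import math

import numpy as np
import pytest

from medreba.errors import DegenerateGeometryError, ProjectionError
from medreba.head_pose import (CameraIntrinsics, FaceModel, HeadPose,
                               estimate_head_pose, euler_from_matrix,
                               euler_to_matrix, matrix_to_rodrigues,
                               neck_angle, project_points,
                               rodrigues_to_matrix)

INTR = CameraIntrinsics.default_for(1280, 720)


def quat_rotation_matrix(rvec):
    """Independent axis-angle -> matrix oracle via unit quaternions."""
    v = np.asarray(rvec, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-300:
        return np.eye(3)
    w = math.cos(theta / 2.0)
    x, y, z = math.sin(theta / 2.0) * v / theta
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestRodrigues:
    def test_zero_vector_identity(self):
        assert np.allclose(rodrigues_to_matrix((0, 0, 0)), np.eye(3))

    def test_quarter_turn_about_z(self):
        R = rodrigues_to_matrix((0, 0, math.pi / 2))
        assert np.allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_orthonormal_det_one(self, rng):
        for _ in range(50):
            R = rodrigues_to_matrix(rng.normal(0, 1, 3))
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_against_quaternion_oracle(self, rng):
        for _ in range(1000):
            v = rng.normal(0, 1, 3) * rng.uniform(0, math.pi)
            assert np.allclose(rodrigues_to_matrix(v),
                               quat_rotation_matrix(v), atol=1e-12)

    def test_round_trip(self, rng):
        for _ in range(1000):
            v = rng.normal(0, 1, 3) * rng.uniform(0, math.pi)
            R = rodrigues_to_matrix(v)
            R2 = rodrigues_to_matrix(matrix_to_rodrigues(R))
            assert np.abs(R - R2).max() < 1e-9

    def test_near_pi_rotation(self):
        v = np.array([0.0, math.pi - 1e-8, 0.0])
        R2 = rodrigues_to_matrix(matrix_to_rodrigues(rodrigues_to_matrix(v)))
        assert np.allclose(rodrigues_to_matrix(v), R2, atol=1e-6)


class TestEuler:
    def test_identity(self):
        assert euler_from_matrix(np.eye(3))[:3] == (0.0, 0.0, 0.0)

    def test_pure_pitch(self):
        p, y, r, lock = euler_from_matrix(euler_to_matrix(30, 0, 0))
        assert (p, y, r) == (pytest.approx(30), pytest.approx(0.0, abs=1e-9),
                             pytest.approx(0.0, abs=1e-9))
        assert not lock

    def test_compose_decompose_round_trip(self, rng):
        for _ in range(300):
            pyr = rng.uniform(-80, 80, 3)
            R = euler_to_matrix(*pyr)
            back = euler_from_matrix(R)[:3]
            assert np.allclose(back, pyr, atol=1e-6)
            assert np.allclose(euler_to_matrix(*back), R, atol=1e-8)

    def test_matches_scipy_intrinsic_xyz(self, rng):
        from scipy.spatial.transform import Rotation
        for _ in range(100):
            pyr = rng.uniform(-80, 80, 3)
            R_scipy = Rotation.from_euler("XYZ", pyr, degrees=True).as_matrix()
            assert np.allclose(euler_to_matrix(*pyr), R_scipy, atol=1e-12)

    def test_gimbal_lock_flagged(self):
        R = euler_to_matrix(25, 90, 40)
        p, y, r, lock = euler_from_matrix(R)
        assert lock
        assert r == 0.0
        assert np.allclose(euler_to_matrix(p, y, r), R, atol=1e-8)

    def test_axis_angle_to_euler_composition(self, rng):
        # euler_from_matrix(rodrigues_to_matrix(v)) equals the direct
        # quaternion-oracle-to-Euler path
        for _ in range(200):
            v = rng.normal(0, 0.5, 3)
            ours = euler_from_matrix(rodrigues_to_matrix(v))[:3]
            oracle = euler_from_matrix(quat_rotation_matrix(v))[:3]
            assert np.allclose(ours, oracle, atol=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            euler_from_matrix(np.eye(3) * 2.0)


class TestProjection:
    def test_optical_axis_hits_principal_point(self):
        img = project_points([[0, 0, 1.0]], np.zeros(3), np.zeros(3), INTR)
        assert np.allclose(img[0], INTR.principal_point)

    def test_focal_scales_offsets(self):
        wide = CameraIntrinsics(focal=2560, principal_point=(640, 360))
        p = [[0.1, 0.05, 1.0]]
        off1 = project_points(p, np.zeros(3), np.zeros(3), INTR)[0] - (640, 360)
        off2 = project_points(p, np.zeros(3), np.zeros(3), wide)[0] - (640, 360)
        assert np.allclose(off2, 2 * off1)

    def test_behind_camera_rejected(self):
        with pytest.raises(ProjectionError):
            project_points([[0, 0, -1.0]], np.zeros(3), np.zeros(3), INTR)

    def test_matches_homogeneous_matrix_oracle(self, rng):
        # zero-distortion pinhole vs explicit K [R|t] arithmetic
        K = np.array([[INTR.focal, 0, INTR.principal_point[0]],
                      [0, INTR.focal, INTR.principal_point[1]],
                      [0, 0, 1.0]])
        for _ in range(100):
            rvec = rng.normal(0, 0.3, 3)
            t = np.array([rng.normal(0, 0.2), rng.normal(0, 0.2),
                          rng.uniform(2, 5)])
            pts = rng.normal(0, 0.3, (4, 3))
            R = quat_rotation_matrix(rvec)
            hom = (K @ (pts @ R.T + t).T).T
            oracle = hom[:, :2] / hom[:, 2:3]
            ours = project_points(pts, rvec, t, INTR)
            assert np.abs(ours - oracle).max() < 1e-9


class TestEstimateHeadPose:
    model = FaceModel()

    def _observe(self, pitch, yaw, roll, dist=3.0, noise=0.0, rng=None):
        R = euler_to_matrix(pitch, yaw, roll)
        pts = self.model.model_points @ R.T + (0, 0, dist)
        img = project_points(pts, np.zeros(3), np.zeros(3), INTR)
        if noise:
            img = img + rng.normal(0, noise, img.shape) * (1280, 720)
        return img

    def test_identity_recovered(self):
        pose = estimate_head_pose(self._observe(0, 0, 0), self.model, INTR)
        assert abs(pose.pitch) < 0.5
        assert abs(pose.yaw) < 0.5
        assert abs(pose.roll) < 0.5

    def test_known_pose_recovered(self):
        pose = estimate_head_pose(self._observe(25, 10, 0), self.model, INTR)
        assert pose.pitch == pytest.approx(25, abs=1.0)
        assert pose.yaw == pytest.approx(10, abs=1.0)
        assert pose.reprojection_rms < 1e-6

    def test_rotation_matrix_valid(self):
        pose = estimate_head_pose(self._observe(-15, 20, 5), self.model, INTR)
        R = pose.rotation_matrix
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(euler_to_matrix(pose.pitch, pose.yaw, pose.roll),
                           R, atol=1e-6)

    def test_collinear_points_rejected(self):
        obs = np.column_stack([np.linspace(100, 200, 6),
                               np.linspace(100, 300, 6)])
        with pytest.raises(DegenerateGeometryError):
            estimate_head_pose(obs, self.model, INTR)

    def test_recovery_under_noise(self, rng):
        # median absolute pitch error < 2 deg over 200 noisy random poses
        errors = []
        for _ in range(200):
            pitch, yaw, roll = rng.uniform(-45, 45, 3)
            obs = self._observe(pitch, yaw, roll, dist=rng.uniform(2, 5),
                                noise=0.002, rng=rng)
            pose = estimate_head_pose(obs, self.model, INTR)
            errors.append(abs(pose.pitch - pitch))
        assert float(np.median(errors)) < 2.0


class TestNeckAngle:
    pose = HeadPose(rotation_vector=np.zeros(3), rotation_matrix=np.eye(3),
                    pitch=15.0, yaw=0.0, roll=0.0)

    def test_absolute(self):
        assert neck_angle(self.pose, reference="absolute") == 15.0

    def test_trunk_relative(self):
        pose = HeadPose(rotation_vector=np.zeros(3),
                        rotation_matrix=np.eye(3), pitch=35.0, yaw=0.0,
                        roll=0.0)
        assert neck_angle(pose, trunk_flexion=20.0,
                          reference="trunk_relative") == 15.0

    def test_grades_downstream(self):
        from medreba.reba_core import grade_neck
        pose = HeadPose(rotation_vector=np.zeros(3),
                        rotation_matrix=np.eye(3), pitch=25.0, yaw=0.0,
                        roll=0.0)
        assert grade_neck(neck_angle(pose)) == 2

    def test_unknown_reference(self):
        with pytest.raises(ValueError):
            neck_angle(self.pose, reference="sideways")
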