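"""Segment frames, hip-joint-center regression and Cardan angles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from limbaug.datamodel import MarkerSequence
from limbaug.kinematics import (
    JointAngleSeries,
    cardan_zxy,
    compose_cardan_zxy,
    hip_joint_center,
    joint_angles,
    pelvis_frame,
    segment_frames,
)
from limbaug.preprocess import substitute_sacr


class TestPelvisFrame:
    def test_hand_constructed_geometry(self):
        # ASISs split along world X, SACR displaced in -Z: the pelvis Z
        # (right) axis is world X and the anterior axis is world Z; the
        # up axis follows from right-handedness (Y = Z x X).
        frame = pelvis_frame(np.array([[-0.1, 1.0, 0.0]]),
                             np.array([[0.1, 1.0, 0.0]]),
                             np.array([[0.0, 1.0, -0.15]]))
        R = frame.rotation[0]
        assert np.allclose(R[:, 2], [1, 0, 0], atol=1e-12)   # Z
        assert np.allclose(R[:, 0], [0, 0, 1], atol=1e-12)   # X anterior
        assert np.allclose(R[:, 1], np.cross(R[:, 2], R[:, 0]))
        assert np.allclose(frame.origin[0], [0, 1, 0])

    def test_orthonormal_proper(self, rng):
        pts = rng.normal(size=(3, 10, 3))
        frame = pelvis_frame(*pts)
        for R in frame.rotation:
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert np.isclose(np.linalg.det(R), 1.0)

    def test_equivariance_under_rotation(self, rng):
        pts = rng.normal(size=(3, 5, 3))
        Q = Rotation.random(random_state=3).as_matrix()
        base = pelvis_frame(*pts).rotation
        moved = pelvis_frame(*(p @ Q.T for p in pts)).rotation
        assert np.allclose(moved, Q @ base, atol=1e-9)

    def test_collinear_points_rejected(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[1.0, 0, 0]])
        c = np.array([[2.0, 0, 0]])
        with pytest.raises(ValueError, match="frame 0"):
            pelvis_frame(a, b, c)


class TestHipJointCenter:
    def test_regression_arithmetic(self):
        # PW = 240 mm, PD = 100 mm with the default coefficient table
        l_asis = np.array([[0.0, 0.0, -0.12]])
        r_asis = np.array([[0.0, 0.0, 0.12]])
        sacr = np.array([[-0.10, 0.0, 0.0]])
        hjc = hip_joint_center(l_asis, r_asis, sacr)
        # pelvis frame is the identity here, origin at 0
        assert np.allclose(hjc["R"][0] * 1000, [-33.9, -82.9, 86.5])
        assert np.allclose(hjc["L"][0] * 1000, [-33.9, -82.9, -86.5])

    def test_mirror_symmetry_and_rigidity(self, rng):
        # rigid pelvis motion: HJC constant in the pelvis frame
        offsets = {"L-ASIS": np.array([0.0, 0.0, -0.12]),
                   "R-ASIS": np.array([0.0, 0.0, 0.12]),
                   "SACR": np.array([-0.1, 0.0, 0.0])}
        T = 6
        Q = Rotation.random(T, random_state=1).as_matrix()
        t = rng.normal(size=(T, 3))
        pts = {k: (Q @ v) + t for k, v in offsets.items()}
        hjc = hip_joint_center(pts["L-ASIS"], pts["R-ASIS"], pts["SACR"])
        frame = pelvis_frame(pts["L-ASIS"], pts["R-ASIS"], pts["SACR"])
        for side in "LR":
            local = np.einsum("tji,tj->ti", frame.rotation,
                              hjc[side] - frame.origin)
            assert np.ptp(local, axis=0).max() < 1e-9
        lloc = np.einsum("tji,tj->ti", frame.rotation,
                         hjc["L"] - frame.origin)
        rloc = np.einsum("tji,tj->ti", frame.rotation,
                         hjc["R"] - frame.origin)
        assert np.allclose(lloc * [1, 1, -1], rloc, atol=1e-12)

    def test_degenerate_width_rejected(self):
        p = np.array([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            hip_joint_center(p, p, np.array([[-0.1, 0.0, 0.0]]))


class TestCardan:
    def test_identity(self):
        assert np.allclose(cardan_zxy(np.eye(3)), [0, 0, 0])

    def test_composition_order(self):
        R = compose_cardan_zxy(30.0, 10.0, 5.0)
        assert np.allclose(cardan_zxy(R), [30, 10, 5], atol=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_recomposition_identity(self, seed):
        """Decompose-then-recompose reproduces any rotation matrix."""
        R = Rotation.random(random_state=seed).as_matrix()
        fe, ab, rot = cardan_zxy(R)
        assert np.abs(compose_cardan_zxy(fe, ab, rot) - R).max() < 1e-9
        assert -90.0 <= ab <= 90.0

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            cardan_zxy(np.eye(3) * 2.0)

    def test_gimbal_flagged_not_fatal(self, caplog):
        R = compose_cardan_zxy(20.0, 89.9, 10.0)
        with caplog.at_level("WARNING"):
            out = cardan_zxy(R)
        assert np.isfinite(out).all()
        assert "gimbal" in caplog.text


class TestJointAngles:
    def test_neutral_pose_zero_angles(self, profile):
        from limbaug.synthetic import (
            SkeletonTemplate, forward_kinematics)
        template = SkeletonTemplate(height=profile.height)
        angles = np.zeros((3, 3, 3, 2))
        origin = np.tile([0.0, 0.93, 0.0], (3, 1))
        R = np.tile(np.eye(3), (3, 1, 1))
        landmarks, _ = forward_kinematics(template, angles, origin, R)
        from limbaug.datamodel import LANDMARKS_RAW
        seq = substitute_sacr(
            MarkerSequence(LANDMARKS_RAW, landmarks, 30.0))
        out = joint_angles(seq)
        assert np.abs(out.angles).max() < 1e-6
        # every segment frame equals the pelvis orientation
        frames = segment_frames(seq)
        for name, fr in frames.items():
            assert np.allclose(fr.rotation, np.eye(3), atol=1e-9), name

    def test_invariant_under_global_rigid_motion(self, gait_trial):
        seq = substitute_sacr(gait_trial.landmarks)
        base = joint_angles(seq).angles
        Q = Rotation.random(random_state=7).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        moved = seq.with_positions(seq.positions @ Q.T + t)
        assert np.abs(joint_angles(moved).angles - base).max() < 1e-9

    def test_mirror_swaps_sides_exactly(self, gait_trial):
        seq = substitute_sacr(gait_trial.landmarks)
        base = joint_angles(seq)
        # reflect across the sagittal (X-Y) plane and swap L/R labels
        names = [n.replace("L-", "#-").replace("R-", "L-")
                 .replace("#-", "R-") for n in seq.point_names]
        mirrored = MarkerSequence(
            names, seq.positions * np.array([1.0, 1.0, -1.0]), seq.fps)
        out = joint_angles(mirrored)
        for j in range(3):
            for a in range(3):
                assert np.allclose(out.angles[:, j, a, 0],
                                   base.angles[:, j, a, 1], atol=1e-9)
                assert np.allclose(out.angles[:, j, a, 1],
                                   base.angles[:, j, a, 0], atol=1e-9)

    def test_fk_round_trip_recovers_script(self, gait_trial):
        seq = substitute_sacr(gait_trial.landmarks)
        rec = joint_angles(seq)
        err = np.abs(rec.angles - gait_trial.true_angles.angles).max()
        assert err < 1e-6

    def test_missing_landmark_rejected(self, gait_trial):
        seq = substitute_sacr(gait_trial.landmarks)
        partial = seq.subset([n for n in seq.point_names if n != "L-LFE"])
        with pytest.raises(KeyError, match="L-LFE"):
            joint_angles(partial)


class TestJointAngleSeries:
    def test_dataframe_round_trip(self, gait_trial):
        series = gait_trial.true_angles
        df = series.to_dataframe()
        assert {"L_hip_FE", "R_ankle_ROT"} <= set(df.columns)
        back = JointAngleSeries.from_dataframe(df, fps=series.fps)
        assert np.allclose(back.angles, series.angles)
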