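"""ISB anatomical frames and lower-limb Cardan joint angles.

Segment frames are built directly from the 17 processed anatomical
landmarks (pelvis, femur, shank and foot per side).  Joint angles are the
Cardan Z–X'–Y'' decomposition of the child-relative-to-parent rotation:
flexion–extension (FE) about Z, abduction–adduction (AB-AD) about the
rotated X, axial rotation (ROT) about the twice-rotated Y.  Left-side
AB-AD/ROT signs are flipped so that positive always means adduction /
internal rotation on both sides.

The hip joint center is regressed from pelvis width and depth
(Harrington-style coefficients by default; the table is configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .datamodel import LANDMARKS_PROCESSED, MarkerSequence

__all__ = [
    "SegmentFrameSeries",
    "JointAngleSeries",
    "HJC_COEFFICIENTS",
    "pelvis_frame",
    "hip_joint_center",
    "segment_frames",
    "cardan_zxy",
    "compose_cardan_zxy",
    "joint_angles",
    "JOINTS",
    "AXES",
    "SIDES",
]

logger = logging.getLogger(__name__)

JOINTS = ("hip", "knee", "ankle")
AXES = ("FE", "AB-AD", "ROT")
SIDES = ("L", "R")

#: Hip-joint-center regression (meters): offset in the pelvis frame as an
#: affine function of pelvis depth (PD) and width (PW),
#: ``x = a_pd * PD + a_pw * PW + b`` per component.  The lateral (z)
#: component takes a + sign on the right side and − on the left.
HJC_COEFFICIENTS = {
    "x": (-0.24, 0.0, -0.0099),
    "y": (0.0, -0.30, -0.0109),
    "z": (0.0, 0.33, 0.0073),
}

_ORTHO_TOL = 1e-9
_GIMBAL_DEG = 89.5


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    """Normalize along the last axis, raising on (near-)zero norm."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    bad = np.nonzero(n[..., 0] < 1e-12)[0]
    if bad.size:
        raise ValueError(
            f"degenerate geometry: zero-length {what} at frame {bad[0]}"
        )
    return v / n


@dataclass
class SegmentFrameSeries:
    """Per-frame pose of one body segment.

    ``rotation[t]`` columns are the segment's X (anterior), Y (proximal/up)
    and Z (right) axes expressed in the world frame; always a proper
    rotation (orthonormal, det +1).
    """

    segment: str
    origin: np.ndarray    # (T, 3) m
    rotation: np.ndarray  # (T, 3, 3)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        T = self.origin.shape[0]
        if self.rotation.shape != (T, 3, 3):
            raise ValueError("rotation must have shape (T, 3, 3)")
        RtR = np.einsum("tij,tik->tjk", self.rotation, self.rotation)
        err = np.abs(RtR - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(
                f"{self.segment}: non-orthonormal rotation (err {err:.2e})"
            )
        if np.any(np.linalg.det(self.rotation) < 0):
            raise ValueError(f"{self.segment}: left-handed rotation")

    @property
    def n_frames(self) -> int:
        return self.origin.shape[0]


def _frame_from_axes(segment, origin, X, Y, Z) -> SegmentFrameSeries:
    R = np.stack([X, Y, Z], axis=-1)
    return SegmentFrameSeries(segment=segment, origin=origin, rotation=R)


def pelvis_frame(l_asis: np.ndarray, r_asis: np.ndarray,
                 sacr: np.ndarray) -> SegmentFrameSeries:
    """Pelvis anatomical frame from the two ASISs and SACR.

    Origin: ASIS midpoint.  Z: along R-ASIS − L-ASIS (subject's right).
    X: in the ASIS/SACR plane, orthogonal to Z, pointing anteriorly (away
    from SACR).  Y = Z × X completes the right-handed frame.
    """
    l_asis, r_asis, sacr = (np.atleast_2d(np.asarray(a, dtype=float))
                            for a in (l_asis, r_asis, sacr))
    origin = 0.5 * (l_asis + r_asis)
    Z = _unit(r_asis - l_asis, "ASIS axis")
    v = origin - sacr
    proj = v - np.sum(v * Z, axis=-1, keepdims=True) * Z
    X = _unit(proj, "pelvis anterior axis (ASISs and SACR collinear?)")
    Y = np.cross(Z, X)
    return _frame_from_axes("pelvis", origin, X, Y, Z)


def hip_joint_center(l_asis: np.ndarray, r_asis: np.ndarray,
                     sacr: np.ndarray,
                     coefficients: dict = None
                     ) -> Dict[str, np.ndarray]:
    """Per-frame left/right hip joint centers (world coordinates, meters).

    The HJC is a fixed point of the pelvis: its pelvis-frame offset is an
    affine function of pelvis width PW = |R-ASIS − L-ASIS| and depth
    PD = |ASIS midpoint − SACR| (see :data:`HJC_COEFFICIENTS`).
    """
    coeffs = coefficients or HJC_COEFFICIENTS
    pelvis = pelvis_frame(l_asis, r_asis, sacr)
    l_asis, r_asis, sacr = (np.atleast_2d(np.asarray(a, dtype=float))
                            for a in (l_asis, r_asis, sacr))
    pw = np.linalg.norm(r_asis - l_asis, axis=-1)
    pd_ = np.linalg.norm(0.5 * (l_asis + r_asis) - sacr, axis=-1)
    if np.any(pw <= 0) or np.any(pd_ <= 0):
        raise ValueError("pelvis width and depth must be positive")

    def _component(key):
        a_pd, a_pw, b = coeffs[key]
        return a_pd * pd_ + a_pw * pw + b

    x, y, z = _component("x"), _component("y"), _component("z")
    out = {}
    for side, zsign in (("L", -1.0), ("R", 1.0)):
        local = np.stack([x, y, zsign * z], axis=-1)
        world = pelvis.origin + np.einsum("tij,tj->ti", pelvis.rotation,
                                          local)
        out[side] = world
    return out


def _limb_frames(landmarks: MarkerSequence, hjc: Dict[str, np.ndarray]
                 ) -> Dict[str, SegmentFrameSeries]:
    """Femur, shank and foot frames for both sides.

    Medio-lateral (Z) axes always point to the *subject's* right: on the
    right limb Z runs medial→lateral, on the left lateral→medial.
    """
    frames = {}
    for side in SIDES:
        zsign = 1.0 if side == "R" else -1.0
        lfe = landmarks.get(f"{side}-LFE")
        mfe = landmarks.get(f"{side}-MFE")
        lm = landmarks.get(f"{side}-LM")
        mm = landmarks.get(f"{side}-MM")
        cal = landmarks.get(f"{side}-CAL")
        toe = landmarks.get(f"{side}-TOE3")

        knee_center = 0.5 * (lfe + mfe)
        ankle_center = 0.5 * (lm + mm)

        # femur: Y up the shaft (knee -> hip), Z epicondyle axis
        Y = _unit(hjc[side] - knee_center, f"{side} femur axis")
        z_raw = zsign * (lfe - mfe)
        z_orth = z_raw - np.sum(z_raw * Y, axis=-1, keepdims=True) * Y
        Z = _unit(z_orth, f"{side} epicondyle axis")
        X = np.cross(Y, Z)
        frames[f"femur-{side}"] = _frame_from_axes(
            f"femur-{side}", hjc[side], X, Y, Z)

        # shank: Y up the shaft (ankle -> knee), Z malleolar axis
        Y = _unit(knee_center - ankle_center, f"{side} shank axis")
        z_raw = zsign * (lm - mm)
        z_orth = z_raw - np.sum(z_raw * Y, axis=-1, keepdims=True) * Y
        Z = _unit(z_orth, f"{side} malleolar axis")
        X = np.cross(Y, Z)
        frames[f"shank-{side}"] = _frame_from_axes(
            f"shank-{side}", knee_center, X, Y, Z)

        # foot: X along the sole (heel -> toe), Z from the malleolar axis
        Z_raw = zsign * (lm - mm)
        Zf = _unit(Z_raw, f"{side} malleolar axis")
        x_raw = toe - cal
        x_orth = x_raw - np.sum(x_raw * Zf, axis=-1, keepdims=True) * Zf
        X = _unit(x_orth, f"{side} foot axis")
        Y = np.cross(Zf, X)
        frames[f"foot-{side}"] = _frame_from_axes(
            f"foot-{side}", ankle_center, X, Y, Zf)
    return frames


def segment_frames(landmarks: MarkerSequence,
                   hjc: Dict[str, np.ndarray] = None
                   ) -> Dict[str, SegmentFrameSeries]:
    """All seven segment frames from the 17 processed landmarks.

    TRO is carried as a technical marker only; the default anatomical
    frames are computed directly from the landmarks every frame.
    """
    missing = set(LANDMARKS_PROCESSED) - set(landmarks.point_names)
    if missing:
        raise KeyError(f"missing landmarks: {sorted(missing)}")
    l_asis = landmarks.get("L-ASIS")
    r_asis = landmarks.get("R-ASIS")
    sacr = landmarks.get("SACR")
    frames = {"pelvis": pelvis_frame(l_asis, r_asis, sacr)}
    if hjc is None:
        hjc = hip_joint_center(l_asis, r_asis, sacr)
    frames.update(_limb_frames(landmarks, hjc))
    return frames


def compose_cardan_zxy(fe_deg: float, abad_deg: float,
                       rot_deg: float) -> np.ndarray:
    """Rotation matrix Rz(FE) · Rx(AB-AD) · Ry(ROT), angles in degrees."""
    a, b, c = np.deg2rad([fe_deg, abad_deg, rot_deg])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Rx = np.array([[1, 0, 0], [0, cb, -sb], [0, sb, cb]])
    Ry = np.array([[cc, 0, sc], [0, 1, 0], [-sc, 0, cc]])
    return Rz @ Rx @ Ry


def cardan_zxy(R: np.ndarray) -> np.ndarray:
    """Decompose rotation(s) as Rz(FE)·Rx(AB-AD)·Ry(ROT), in degrees.

    Accepts (3, 3) or (T, 3, 3).  FE and ROT lie in (−180, 180],
    AB-AD in [−90, 90].  Frames within 0.5° of gimbal lock
    (|AB-AD| > 89.5°) are flagged via a log warning, not an error.
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    if single:
        R = R[None]
    RtR = np.einsum("tij,tik->tjk", R, R)
    if np.abs(RtR - np.eye(3)).max() > 1e-6:
        raise ValueError("cardan_zxy requires orthonormal rotations")
    sb = np.clip(R[:, 2, 1], -1.0, 1.0)
    b = np.arcsin(sb)
    a = np.arctan2(-R[:, 0, 1], R[:, 1, 1])
    c = np.arctan2(-R[:, 2, 0], R[:, 2, 2])
    deg = np.degrees(np.stack([a, b, c], axis=-1))
    near_gimbal = np.abs(deg[:, 1]) > _GIMBAL_DEG
    if near_gimbal.any():
        logger.warning(
            "cardan_zxy: %d frame(s) within 0.5 deg of gimbal lock",
            int(near_gimbal.sum()),
        )
    return deg[0] if single else deg


@dataclass
class JointAngleSeries:
    """Per-frame hip/knee/ankle Cardan angles, degrees, both sides.

    ``angles`` has shape (T, 3 joints, 3 axes, 2 sides) indexed by
    :data:`JOINTS`, :data:`AXES` and :data:`SIDES`.
    """

    angles: np.ndarray
    fps: float
    movement: str = ""

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 4 or self.angles.shape[1:] != (3, 3, 2):
            raise ValueError(
                f"angles must have shape (T, 3, 3, 2), got "
                f"{self.angles.shape}"
            )
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("non-finite joint angle")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def get(self, joint: str, axis: str, side: str) -> np.ndarray:
        return self.angles[:, JOINTS.index(joint), AXES.index(axis),
                           SIDES.index(side)]

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: frame, time, then <side>_<joint>_<axis> in degrees."""
        T = self.n_frames
        data = {"frame": np.arange(1, T + 1),
                "time": np.arange(T) / self.fps}
        for side in SIDES:
            for joint in JOINTS:
                for axis in AXES:
                    data[f"{side}_{joint}_{axis}"] = self.get(
                        joint, axis, side)
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fps: float = None,
                       movement: str = "") -> "JointAngleSeries":
        if fps is None:
            t = df["time"].to_numpy()
            fps = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
        T = len(df)
        arr = np.empty((T, 3, 3, 2))
        for j, joint in enumerate(JOINTS):
            for a, axis in enumerate(AXES):
                for s, side in enumerate(SIDES):
                    arr[:, j, a, s] = df[f"{side}_{joint}_{axis}"].to_numpy()
        return cls(arr, fps, movement)


def joint_angles(landmarks: MarkerSequence) -> JointAngleSeries:
    """Hip, knee and ankle Cardan angles from the 17 processed landmarks.

    hip = femur w.r.t. pelvis, knee = shank w.r.t. femur, ankle = foot
    w.r.t. shank.  Left-side AB-AD and ROT are sign-flipped so positive
    means adduction / internal rotation on both sides.
    """
    frames = segment_frames(landmarks)
    T = landmarks.n_frames
    out = np.empty((T, 3, 3, 2))
    pairs = {
        "hip": ("pelvis", "femur-{s}"),
        "knee": ("femur-{s}", "shank-{s}"),
        "ankle": ("shank-{s}", "foot-{s}"),
    }
    for j, joint in enumerate(JOINTS):
        parent_key, child_key = pairs[joint]
        for s, side in enumerate(SIDES):
            Rp = frames[parent_key.format(s=side)].rotation
            Rc = frames[child_key.format(s=side)].rotation
            R_rel = np.einsum("tji,tjk->tik", Rp, Rc)  # Rpᵀ Rc
            deg = cardan_zxy(R_rel)
            if side == "L":
                deg = deg * np.array([1.0, -1.0, -1.0])
            out[:, j, :, s] = deg
    return JointAngleSeries(out, landmarks.fps, landmarks.movement)
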