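"""Pre-processing: SACR substitution, centering, scaling, normalization,
rotation augmentation, feature assembly and windowing.

The supervised models consume per-frame feature vectors of length 42
(``[sex, weight_norm, height_norm]`` followed by the 13 keypoints in
:data:`~limbaug.datamodel.KEYPOINT_FEATURE_ORDER`, X/Y/Z each) and emit
target vectors of length 51 (the 17 processed landmarks in
:data:`~limbaug.datamodel.LANDMARK_TARGET_ORDER`).  All coordinates are
hip-centered and height-scaled, so features and targets are dimensionless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    KEYPOINT_FEATURE_ORDER,
    LANDMARK_TARGET_ORDER,
    AnthropometricProfile,
    MarkerSequence,
    TrialRecord,
)

__all__ = [
    "NormalizationSpec",
    "CenteringOffsets",
    "substitute_sacr",
    "center_and_scale",
    "invert_centering",
    "normalize_anthropometrics",
    "augment_rotations",
    "rotation_about_vertical",
    "assemble_features",
    "features_to_landmarks",
    "make_windows",
    "N_FEATURES",
    "N_TARGETS",
]

logger = logging.getLogger(__name__)

N_FEATURES = 3 + 3 * len(KEYPOINT_FEATURE_ORDER)   # 42
N_TARGETS = 3 * len(LANDMARK_TARGET_ORDER)         # 51

#: Hip-midpoint tolerance (scaled units) below which a trial counts as
#: centered.
_CENTERED_ATOL = 1e-7


@dataclass(frozen=True)
class NormalizationSpec:
    """Min–max ranges for the anthropometric inputs.

    The ranges are computed over a training manifest and stored with every
    trained model so inference reuses the exact training-time mapping.
    """

    height_range: Tuple[float, float]
    weight_range: Tuple[float, float]
    vertical_axis: Tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("height", self.height_range),
                               ("weight", self.weight_range)):
            if not lo < hi:
                raise ValueError(f"{name}_range must satisfy min < max, "
                                 f"got ({lo}, {hi})")

    @classmethod
    def from_profiles(cls,
                      profiles: Iterable[AnthropometricProfile]
                      ) -> "NormalizationSpec":
        profiles = list(profiles)
        if not profiles:
            raise ValueError("no profiles given")
        h = [p.height for p in profiles]
        w = [p.weight for p in profiles]
        hr = (min(h), max(h))
        wr = (min(w), max(w))
        if hr[0] == hr[1]:
            hr = (hr[0] - 0.01, hr[1] + 0.01)
        if wr[0] == wr[1]:
            wr = (wr[0] - 1.0, wr[1] + 1.0)
        return cls(height_range=hr, weight_range=wr)

    def to_json(self) -> str:
        return json.dumps({
            "height_range": list(self.height_range),
            "weight_range": list(self.weight_range),
            "vertical_axis": list(self.vertical_axis),
        })

    @classmethod
    def from_json(cls, payload: str) -> "NormalizationSpec":
        d = json.loads(payload)
        return cls(height_range=tuple(d["height_range"]),
                   weight_range=tuple(d["weight_range"]),
                   vertical_axis=tuple(d.get("vertical_axis", (0, 1, 0))))


@dataclass
class CenteringOffsets:
    """Per-frame hip-midpoint positions and the height used for scaling.

    Stored so model predictions (scaled, hip-centered) can be mapped back
    to world coordinates.
    """

    hip_midpoint: np.ndarray  # (T, 3) meters
    height: float             # meters

    def __post_init__(self) -> None:
        self.hip_midpoint = np.asarray(self.hip_midpoint, dtype=float)
        if self.hip_midpoint.ndim != 2 or self.hip_midpoint.shape[1] != 3:
            raise ValueError("hip_midpoint must have shape (T, 3)")
        if not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")


def substitute_sacr(landmarks: MarkerSequence) -> MarkerSequence:
    """Replace the L/R-PSIS pair with SACR, their per-frame midpoint.

    Idempotent: a sequence already carrying SACR (and no PSIS) is returned
    unchanged.
    """
    names = landmarks.point_names
    if "SACR" in names and "L-PSIS" not in names and "R-PSIS" not in names:
        return landmarks
    for psis in ("L-PSIS", "R-PSIS"):
        if psis not in names:
            raise KeyError(f"cannot build SACR: {psis!r} absent")
    sacr = 0.5 * (landmarks.get("L-PSIS") + landmarks.get("R-PSIS"))
    keep = [n for n in names if n not in ("L-PSIS", "R-PSIS")]
    idx = [landmarks.index(n) for n in keep]
    pos = np.concatenate(
        [landmarks.positions[:, idx, :], sacr[:, None, :]], axis=1
    )
    return MarkerSequence(keep + ["SACR"], pos, landmarks.fps,
                          landmarks.movement)


def _hip_midpoint(keypoints: MarkerSequence) -> np.ndarray:
    return 0.5 * (keypoints.get("L-hip") + keypoints.get("R-hip"))


def center_and_scale(trial: TrialRecord) -> Tuple[TrialRecord,
                                                  CenteringOffsets]:
    """Express all points relative to the hip-keypoint midpoint and divide
    by subject height.

    Returns the transformed trial and the offsets needed to invert the
    transform (:func:`invert_centering`).
    """
    height = trial.profile.height
    if not height > 0:
        raise ValueError(f"non-positive subject height {height}")
    hip_mid = _hip_midpoint(trial.keypoints)
    offsets = CenteringOffsets(hip_midpoint=hip_mid, height=height)

    def _transform(seq: MarkerSequence) -> MarkerSequence:
        return seq.with_positions(
            (seq.positions - hip_mid[:, None, :]) / height
        )

    new = replace(
        trial,
        keypoints=_transform(trial.keypoints),
        landmarks=None if trial.landmarks is None
        else _transform(trial.landmarks),
    )
    return new, offsets


def invert_centering(seq: MarkerSequence,
                     offsets: CenteringOffsets) -> MarkerSequence:
    """Undo :func:`center_and_scale` for one marker sequence."""
    if seq.n_frames != offsets.hip_midpoint.shape[0]:
        raise ValueError(
            f"sequence has {seq.n_frames} frames but offsets have "
            f"{offsets.hip_midpoint.shape[0]}"
        )
    return seq.with_positions(
        seq.positions * offsets.height + offsets.hip_midpoint[:, None, :]
    )


def normalize_anthropometrics(profile: AnthropometricProfile,
                              spec: NormalizationSpec
                              ) -> Tuple[float, float]:
    """Min–max normalize height and weight against the spec's ranges.

    Values outside the range extrapolate beyond [0, 1]; this is allowed but
    logged, since it means the subject falls outside the training cohort.
    """
    out = []
    for name, value, (lo, hi) in (
        ("height", profile.height, spec.height_range),
        ("weight", profile.weight, spec.weight_range),
    ):
        norm = (value - lo) / (hi - lo)
        if not 0.0 <= norm <= 1.0:
            logger.warning(
                "%s %.3f of subject %s outside normalization range (%g, %g)",
                name, value, profile.subject_id, lo, hi,
            )
        out.append(norm)
    return out[0], out[1]


def rotation_about_vertical(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the canonical vertical axis (+Y)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s],
                     [0.0, 1.0, 0.0],
                     [-s, 0.0, c]])


def _assert_centered(trial: TrialRecord) -> None:
    hip_mid = _hip_midpoint(trial.keypoints)
    worst = np.abs(hip_mid).max()
    if worst > _CENTERED_ATOL:
        raise ValueError(
            "trial is not hip-centered (max |hip midpoint| = "
            f"{worst:.3e}); rotation augmentation requires centering first"
        )


def augment_rotations(trial: TrialRecord,
                      angles_deg: Sequence[float]) -> List[TrialRecord]:
    """Rotate a centered trial about the vertical axis, one copy per angle.

    The same rotation is applied to keypoints and landmarks, so the
    keypoint-landmark pairing (and every inter-point distance) is preserved.
    Angle 0 reproduces the input.
    """
    _assert_centered(trial)
    out = []
    for angle in angles_deg:
        R = rotation_about_vertical(angle)

        def _rot(seq: MarkerSequence) -> MarkerSequence:
            return seq.with_positions(seq.positions @ R.T)

        out.append(replace(
            trial,
            keypoints=_rot(trial.keypoints),
            landmarks=None if trial.landmarks is None
            else _rot(trial.landmarks),
        ))
    return out


def default_augmentation_angles(n: int = 8) -> np.ndarray:
    """``n`` rotations evenly spaced over [0°, 360°)."""
    return np.arange(n) * (360.0 / n)


def assemble_features(trial: TrialRecord,
                      spec: NormalizationSpec,
                      ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Build per-frame model inputs (T, 42) and targets (T, 51).

    The trial must already be hip-centered and height-scaled; landmark
    targets (when present) must be SACR-substituted.  Feature ordering is
    fixed: ``[sex, weight_norm, height_norm]`` then keypoints alphabetically,
    X/Y/Z per point; targets are the 17 landmarks alphabetically.
    """
    _assert_centered(trial)
    kp = trial.keypoints
    if set(kp.point_names) != set(KEYPOINT_FEATURE_ORDER):
        raise ValueError(
            f"expected the {len(KEYPOINT_FEATURE_ORDER)} configured "
            f"keypoints, got {len(kp.point_names)}: {kp.point_names}"
        )
    h_norm, w_norm = normalize_anthropometrics(trial.profile, spec)
    T = kp.n_frames
    anthro = np.tile(
        [float(trial.profile.sex_code), w_norm, h_norm], (T, 1)
    )
    kp_flat = kp.reordered(KEYPOINT_FEATURE_ORDER).positions.reshape(T, -1)
    X = np.concatenate([anthro, kp_flat], axis=1)
    assert X.shape[1] == N_FEATURES

    Y = None
    if trial.landmarks is not None:
        lm = trial.landmarks
        if set(lm.point_names) != set(LANDMARK_TARGET_ORDER):
            raise ValueError(
                f"expected the {len(LANDMARK_TARGET_ORDER)} processed "
                f"landmarks (SACR-substituted), got {len(lm.point_names)}"
            )
        Y = lm.reordered(LANDMARK_TARGET_ORDER).positions.reshape(T, -1)
        assert Y.shape[1] == N_TARGETS
    return X, Y


def features_to_landmarks(Y: np.ndarray, fps: float,
                          movement: str = "") -> MarkerSequence:
    """Inverse of the target flattening: (T, 51) -> 17-point sequence
    (still in centered/scaled coordinates)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != N_TARGETS:
        raise ValueError(f"expected (T, {N_TARGETS}) targets, got {Y.shape}")
    pos = Y.reshape(Y.shape[0], len(LANDMARK_TARGET_ORDER), 3)
    return MarkerSequence(LANDMARK_TARGET_ORDER, pos, fps, movement)


@dataclass
class Window:
    """A fixed-length slice of per-frame vectors.

    ``start`` is the index of the first *real* frame covered; ``n_padded``
    leading frames are repeats of the first frame (used when the trial is
    shorter than the window).
    """

    features: np.ndarray            # (length, F)
    start: int
    n_padded: int = 0
    targets: Optional[np.ndarray] = None

    @property
    def padded(self) -> bool:
        return self.n_padded > 0


def make_windows(X: np.ndarray, length: int, stride: int = 1,
                 Y: Optional[np.ndarray] = None) -> List[Window]:
    """Cut per-frame arrays into overlapping windows of ``length`` frames.

    A trial shorter than ``length`` yields a single window left-padded by
    repeating the first frame, with the padding flagged.
    """
    if length < 1 or stride < 1:
        raise ValueError("length and stride must be >= 1")
    X = np.asarray(X)
    T = X.shape[0]
    if T < length:
        pad = length - T
        Xw = np.concatenate([np.repeat(X[:1], pad, axis=0), X], axis=0)
        Yw = None
        if Y is not None:
            Yw = np.concatenate([np.repeat(Y[:1], pad, axis=0), Y], axis=0)
        return [Window(features=Xw, start=0, n_padded=pad, targets=Yw)]
    out = []
    for start in range(0, T - length + 1, stride):
        sl = slice(start, start + length)
        out.append(Window(
            features=X[sl], start=start, n_padded=0,
            targets=None if Y is None else Y[sl],
        ))
    return out
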