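"""Core domain containers for marker-based and markerless motion data.

Conventions used throughout the package:

* Canonical units: meters, degrees, Hz.
* Canonical axes: right-handed with X anterior, Y vertical (up) and Z to
  the subject's right (ISB-style).  Importers may rotate from a declared
  Z-up convention on load, see :mod:`limbaug.io`.
* Time is implicit: frame index divided by ``fps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MarkerSequence",
    "AnthropometricProfile",
    "TrialRecord",
    "DatasetManifest",
    "MOVEMENTS",
    "MOVEMENT_FPS",
    "DEFAULT_KEYPOINTS",
    "LANDMARKS_RAW",
    "LANDMARKS_PROCESSED",
    "KEYPOINT_FEATURE_ORDER",
    "LANDMARK_TARGET_ORDER",
]

#: The eight capture conditions and their native frame rates (Hz).
MOVEMENT_FPS = {
    "A-pose": 30.0,
    "gait": 60.0,
    "running": 60.0,
    "squats": 30.0,
    "j-jacks": 30.0,
    "jump": 60.0,
    "f-jump": 30.0,
    "t-jump": 30.0,
}

MOVEMENTS = tuple(MOVEMENT_FPS)

#: Default 13 lower-body pose-network keypoints.  Only L/R-hip are
#: functionally required (hip-midpoint centering); the rest are configurable.
DEFAULT_KEYPOINTS = (
    "nose",
    "L-shoulder",
    "R-shoulder",
    "L-hip",
    "R-hip",
    "L-knee",
    "R-knee",
    "L-ankle",
    "R-ankle",
    "L-heel",
    "R-heel",
    "L-foot_index",
    "R-foot_index",
)

#: The 18 raw anatomical landmarks (before SACR substitution).
LANDMARKS_RAW = (
    "L-ASIS", "R-ASIS",
    "L-PSIS", "R-PSIS",
    "L-TRO", "R-TRO",
    "L-LFE", "R-LFE",
    "L-MFE", "R-MFE",
    "L-LM", "R-LM",
    "L-MM", "R-MM",
    "L-CAL", "R-CAL",
    "L-TOE3", "R-TOE3",
)

#: The 17 processed landmarks: the PSIS pair is replaced by SACR, their
#: per-frame midpoint.
LANDMARKS_PROCESSED = tuple(
    n for n in LANDMARKS_RAW if n not in ("L-PSIS", "R-PSIS")
) + ("SACR",)

#: Fixed feature ordering: keypoints sorted alphabetically by canonical name,
#: X, Y, Z per point.  Together with [sex, weight_norm, height_norm] this
#: defines the 42-long model input vector.
KEYPOINT_FEATURE_ORDER = tuple(sorted(DEFAULT_KEYPOINTS))

#: Fixed target ordering: the 17 processed landmarks sorted alphabetically,
#: X, Y, Z per point — the 51-long model output vector.
LANDMARK_TARGET_ORDER = tuple(sorted(LANDMARKS_PROCESSED))


@dataclass
class MarkerSequence:
    """Named 3D point trajectories (keypoints or landmarks).

    Parameters
    ----------
    point_names : sequence of str
        Ordered point labels; no duplicates.
    positions : ndarray, shape (T, P, 3)
        Coordinates in meters, canonical Y-up axes.
    fps : float
        Frames per second, > 0.
    movement : str
        Movement label (one of :data:`MOVEMENTS` or free text).
    """

    point_names: Sequence[str]
    positions: np.ndarray
    fps: float
    movement: str = ""

    def __post_init__(self) -> None:
        self.point_names = tuple(str(n) for n in self.point_names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValueError(
                f"positions must have shape (T, P, 3), got {pos.shape}"
            )
        self.positions = pos
        if len(set(self.point_names)) != len(self.point_names):
            raise ValueError("duplicate point names")
        if pos.shape[1] != len(self.point_names):
            raise ValueError(
                f"positions has {pos.shape[1]} points but "
                f"{len(self.point_names)} names were given"
            )
        if pos.shape[0] < 1:
            raise ValueError("at least one frame required")
        if len(self.point_names) < 1:
            raise ValueError("at least one point required")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.all(np.isfinite(pos)):
            t, p, _ = np.argwhere(~np.isfinite(pos))[0]
            raise ValueError(
                f"non-finite coordinate at frame {t}, marker "
                f"{self.point_names[p]!r}"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_points(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds (T / fps)."""
        return self.n_frames / self.fps

    def index(self, name: str) -> int:
        try:
            return self.point_names.index(name)
        except ValueError:
            raise KeyError(f"point {name!r} not in sequence") from None

    def get(self, name: str) -> np.ndarray:
        """Trajectory of a single point, shape (T, 3)."""
        return self.positions[:, self.index(name), :]

    def has(self, name: str) -> bool:
        return name in self.point_names

    def subset(self, names: Sequence[str]) -> "MarkerSequence":
        idx = [self.index(n) for n in names]
        return MarkerSequence(
            tuple(names), self.positions[:, idx, :].copy(), self.fps,
            self.movement,
        )

    def reordered(self, names: Sequence[str]) -> "MarkerSequence":
        """Same point set in the given order."""
        if set(names) != set(self.point_names):
            missing = set(names) - set(self.point_names)
            raise KeyError(f"cannot reorder: missing points {sorted(missing)}")
        return self.subset(names)

    def with_positions(self, positions: np.ndarray) -> "MarkerSequence":
        return MarkerSequence(self.point_names, positions, self.fps,
                              self.movement)

    def copy(self) -> "MarkerSequence":
        return self.with_positions(self.positions.copy())

    def allclose(self, other: "MarkerSequence", atol: float = 1e-9) -> bool:
        return (
            self.point_names == tuple(other.point_names)
            and self.positions.shape == other.positions.shape
            and np.allclose(self.positions, other.positions, atol=atol)
            and np.isclose(self.fps, other.fps)
        )


@dataclass(frozen=True)
class AnthropometricProfile:
    """Subject anthropometrics used as model inputs.

    ``sex_code`` follows the 0 = female / 1 = male encoding; ``height`` in
    meters, ``weight`` in kilograms.
    """

    subject_id: str
    sex_code: int
    height: float
    weight: float

    def __post_init__(self) -> None:
        if self.sex_code not in (0, 1):
            raise ValueError(f"sex_code must be 0 or 1, got {self.sex_code}")
        if not (0.5 < self.height < 2.5):
            raise ValueError(
                f"height {self.height} m outside plausible range (0.5, 2.5)"
            )
        if not (20.0 < self.weight < 300.0):
            raise ValueError(
                f"weight {self.weight} kg outside plausible range (20, 300)"
            )


@dataclass
class TrialRecord:
    """One motion trial: keypoints, optional paired landmarks, subject info.

    When landmarks are present they must share the keypoints' frame count
    and frame rate (the pairing the supervised models train on).
    """

    subject_id: str
    profile: AnthropometricProfile
    keypoints: MarkerSequence
    landmarks: Optional[MarkerSequence] = None
    #: Ground-truth joint angles, attached by the synthetic generator.
    true_angles: Optional[object] = None

    def __post_init__(self) -> None:
        if self.landmarks is not None:
            if self.landmarks.n_frames != self.keypoints.n_frames:
                raise ValueError(
                    "keypoints and landmarks differ in frame count: "
                    f"{self.keypoints.n_frames} vs {self.landmarks.n_frames}"
                )
            if not np.isclose(self.landmarks.fps, self.keypoints.fps):
                raise ValueError("keypoints and landmarks differ in fps")

    @property
    def movement(self) -> str:
        return self.keypoints.movement

    @property
    def n_frames(self) -> int:
        return self.keypoints.n_frames

    def copy(self) -> "TrialRecord":
        return replace(
            self,
            keypoints=self.keypoints.copy(),
            landmarks=None if self.landmarks is None else self.landmarks.copy(),
        )


@dataclass
class DatasetManifest:
    """A collection of trials with a by-subject train/test split."""

    trials: list = field(default_factory=list)
    #: subject_id -> "train" | "test"
    split: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, tag in self.split.items():
            if tag not in ("train", "test"):
                raise ValueError(f"bad split tag {tag!r} for subject {sid!r}")
        for trial in self.trials:
            if trial.subject_id not in self.split:
                raise ValueError(
                    f"subject {trial.subject_id!r} has no split assignment"
                )

    @property
    def subjects(self) -> tuple:
        seen = dict.fromkeys(t.subject_id for t in self.trials)
        return tuple(seen)

    def _records(self, tag: str) -> list:
        return [t for t in self.trials if self.split[t.subject_id] == tag]

    @property
    def train_trials(self) -> list:
        return self._records("train")

    @property
    def test_trials(self) -> list:
        return self._records("test")

    @property
    def train_subjects(self) -> tuple:
        return tuple(s for s in self.subjects if self.split[s] == "train")

    @property
    def test_subjects(self) -> tuple:
        return tuple(s for s in self.subjects if self.split[s] == "test")
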