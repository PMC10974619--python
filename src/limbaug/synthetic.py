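"""Synthetic paired keypoint/landmark trials.

The generator emulates the statistical structure the pipeline assumes:

* a rigid lower-limb skeleton whose 18 anatomical landmarks are fixed
  points of their parent segments (pelvis, femur, shank, foot), scaled
  linearly with subject height;
* smooth sinusoidal joint-angle scripts per movement, with per-subject
  amplitude jitter, driven through forward kinematics — so the generating
  Cardan angles are known analytically and recoverable by
  :func:`limbaug.kinematics.joint_angles`;
* pose-network keypoints built as fixed convex combinations of landmarks
  plus constant segment-local offsets, corrupted by additive Gaussian
  noise — emulating the systematic offset and triangulation error of
  image-based pose estimation relative to mesh-derived landmarks.

The ankle is generated as a pure hinge (FE only): in the adopted foot-frame
convention the medio-lateral axis is the malleolar axis, which makes the
reconstructed ankle joint a one-degree-of-freedom rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    DEFAULT_KEYPOINTS,
    LANDMARKS_RAW,
    MOVEMENT_FPS,
    MOVEMENTS,
    AnthropometricProfile,
    DatasetManifest,
    MarkerSequence,
    TrialRecord,
)
from .kinematics import (
    AXES,
    HJC_COEFFICIENTS,
    JOINTS,
    SIDES,
    JointAngleSeries,
    compose_cardan_zxy,
)

__all__ = [
    "SkeletonTemplate",
    "MotionScript",
    "NoiseModel",
    "sample_profile",
    "generate_trial",
    "generate_dataset",
    "MOVEMENT_SCRIPTS",
]

#: Reference height (m) at which template offsets are tabulated.
_REF_HEIGHT = 1.75


@dataclass(frozen=True)
class SkeletonTemplate:
    """Segment dimensions and landmark offsets as linear functions of height.

    All lengths are fractions of stature; the numeric values follow common
    anthropometric proportion tables (pelvis ~0.14 H wide, thigh 0.245 H,
    shank 0.246 H, foot 0.152 H).
    """

    height: float
    pelvis_width: float = 0.14      # ASIS-to-ASIS, fraction of height
    pelvis_depth: float = 0.10      # ASIS midpoint to SACR
    psis_halfwidth: float = 0.035
    thigh_length: float = 0.245     # HJC to knee center
    shank_length: float = 0.246     # knee to ankle center
    knee_halfwidth: float = 0.045   # epicondyle half-separation
    ankle_halfwidth: float = 0.04   # malleolus half-separation
    tro_drop: float = 0.03          # TRO below HJC
    tro_lateral: float = 0.055
    heel_back: float = 0.045        # CAL behind ankle center
    toe_front: float = 0.115        # TOE3 ahead of ankle center
    sole_drop: float = 0.055        # CAL/TOE3 below ankle center
    pelvis_height: float = 0.53     # standing pelvis-origin height

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("height must be positive")

    def _s(self, fraction: float) -> float:
        return fraction * self.height

    # -- landmark offsets in their parent segment frames -------------------
    def pelvis_landmarks(self) -> Dict[str, np.ndarray]:
        w2 = self._s(self.pelvis_width) / 2
        d = self._s(self.pelvis_depth)
        p2 = self._s(self.psis_halfwidth)
        return {
            "L-ASIS": np.array([0.0, 0.0, -w2]),
            "R-ASIS": np.array([0.0, 0.0, w2]),
            "L-PSIS": np.array([-d, 0.0, -p2]),
            "R-PSIS": np.array([-d, 0.0, p2]),
        }

    def femur_landmarks(self, side: str) -> Dict[str, np.ndarray]:
        zl = 1.0 if side == "R" else -1.0  # lateral direction
        lt = self._s(self.thigh_length)
        k2 = self._s(self.knee_halfwidth)
        return {
            f"{side}-TRO": np.array([0.0, -self._s(self.tro_drop),
                                     zl * self._s(self.tro_lateral)]),
            f"{side}-LFE": np.array([0.0, -lt, zl * k2]),
            f"{side}-MFE": np.array([0.0, -lt, -zl * k2]),
        }

    def shank_landmarks(self, side: str) -> Dict[str, np.ndarray]:
        zl = 1.0 if side == "R" else -1.0
        ls = self._s(self.shank_length)
        a2 = self._s(self.ankle_halfwidth)
        return {
            f"{side}-LM": np.array([0.0, -ls, zl * a2]),
            f"{side}-MM": np.array([0.0, -ls, -zl * a2]),
        }

    def foot_landmarks(self, side: str) -> Dict[str, np.ndarray]:
        return {
            f"{side}-CAL": np.array([-self._s(self.heel_back),
                                     -self._s(self.sole_drop), 0.0]),
            f"{side}-TOE3": np.array([self._s(self.toe_front),
                                      -self._s(self.sole_drop), 0.0]),
        }

    def hjc_local(self, side: str) -> np.ndarray:
        """Hip joint center in the pelvis frame, via the same regression
        the kinematics module applies (so reconstruction is exact)."""
        pw = self._s(self.pelvis_width)
        pd_ = self._s(self.pelvis_depth)
        comp = {}
        for key, (a_pd, a_pw, b) in HJC_COEFFICIENTS.items():
            comp[key] = a_pd * pd_ + a_pw * pw + b
        zsign = 1.0 if side == "R" else -1.0
        return np.array([comp["x"], comp["y"], zsign * comp["z"]])


# ---------------------------------------------------------------------------
# motion scripts
# ---------------------------------------------------------------------------

#: Physiologic amplitude bounds per axis (degrees).
_AXIS_BOUND = {"FE": 120.0, "AB-AD": 45.0, "ROT": 45.0}


@dataclass(frozen=True)
class Sinusoid:
    """mean + amp * sin(2*pi*freq*t + phase)  [degrees, Hz, radians]."""

    mean: float = 0.0
    amp: float = 0.0
    freq: float = 1.0
    phase: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.mean + self.amp * np.sin(
            2.0 * np.pi * self.freq * t + self.phase)


@dataclass(frozen=True)
class MotionScript:
    """Joint-angle trajectories for one movement.

    ``joints[(joint, axis)]`` holds a :class:`Sinusoid` applied to the right
    side; the left side uses the same waveform shifted by ``left_phase``
    (anti-phase for cyclic locomotion, in phase for symmetric movements).
    Per-subject realizations jitter the amplitudes multiplicatively.
    """

    movement: str
    joints: Dict[Tuple[str, str], Sinusoid] = field(default_factory=dict)
    left_phase: float = 0.0
    forward_speed: float = 0.0      # m/s along +X
    bob_amp: float = 0.0            # vertical pelvis oscillation, m
    bob_freq: float = 2.0
    sway_deg: float = 1.0           # pelvis roll/tilt amplitude
    yaw_deg: float = 2.0            # pelvis yaw amplitude
    yaw_freq: float = 0.5
    amp_jitter: float = 0.1         # per-subject relative amplitude SD

    @property
    def fps(self) -> float:
        return MOVEMENT_FPS.get(self.movement, 30.0)

    def __post_init__(self) -> None:
        for (joint, axis), sin in self.joints.items():
            bound = _AXIS_BOUND[axis]
            if abs(sin.mean) + abs(sin.amp) > bound:
                raise ValueError(
                    f"{self.movement}: {joint} {axis} exceeds physiologic "
                    f"bound {bound} deg"
                )
            if joint == "ankle" and axis != "FE" and sin.amp != 0:
                raise ValueError(
                    "ankle is generated as a pure hinge; AB-AD/ROT "
                    "amplitudes must be zero"
                )

    def realize(self, rng: np.random.Generator) -> "MotionScript":
        """Per-subject realization with jittered amplitudes."""
        new = {}
        for key, sin in self.joints.items():
            factor = 1.0 + self.amp_jitter * rng.standard_normal()
            factor = float(np.clip(factor, 0.5, 1.5))
            new[key] = replace(sin, amp=sin.amp * factor)
        return replace(self, joints=new, amp_jitter=0.0)

    def angle_array(self, t: np.ndarray) -> np.ndarray:
        """Ground-truth angles, shape (T, 3 joints, 3 axes, 2 sides) deg."""
        T = len(t)
        out = np.zeros((T, 3, 3, 2))
        for (joint, axis), sin in self.joints.items():
            j, a = JOINTS.index(joint), AXES.index(axis)
            for s, side in enumerate(SIDES):
                phase = self.left_phase if side == "L" else 0.0
                out[:, j, a, s] = sin(t) if phase == 0.0 else replace(
                    sin, phase=sin.phase + phase)(t)
        return out


def _gait_like(movement, f, hip_fe, knee_fe, ankle_fe, speed,
               hip_aa=5.0, hip_rot=5.0, knee_aa=3.0, knee_rot=4.0,
               bob=0.02, **kw):
    return MotionScript(
        movement=movement,
        joints={
            ("hip", "FE"): Sinusoid(mean=5.0, amp=hip_fe, freq=f),
            ("hip", "AB-AD"): Sinusoid(amp=hip_aa, freq=f, phase=0.7),
            ("hip", "ROT"): Sinusoid(amp=hip_rot, freq=f, phase=1.2),
            ("knee", "FE"): Sinusoid(mean=knee_fe * 0.6, amp=knee_fe * 0.55,
                                     freq=f, phase=0.9),
            ("knee", "AB-AD"): Sinusoid(amp=knee_aa, freq=f, phase=0.4),
            ("knee", "ROT"): Sinusoid(amp=knee_rot, freq=f, phase=1.5),
            ("ankle", "FE"): Sinusoid(amp=ankle_fe, freq=f, phase=2.1),
        },
        left_phase=np.pi,
        forward_speed=speed,
        bob_amp=bob,
        bob_freq=2 * f,
        **kw,
    )


def _jump_like(movement, f, hip_fe, knee_fe, ankle_fe, bob, **kw):
    return MotionScript(
        movement=movement,
        joints={
            ("hip", "FE"): Sinusoid(mean=hip_fe * 0.5, amp=hip_fe * 0.5,
                                    freq=f),
            ("hip", "AB-AD"): Sinusoid(amp=3.0, freq=f, phase=0.5),
            ("hip", "ROT"): Sinusoid(amp=3.0, freq=f, phase=1.0),
            ("knee", "FE"): Sinusoid(mean=knee_fe * 0.5, amp=knee_fe * 0.5,
                                     freq=f, phase=0.3),
            ("knee", "AB-AD"): Sinusoid(amp=2.0, freq=f, phase=0.6),
            ("knee", "ROT"): Sinusoid(amp=3.0, freq=f, phase=1.1),
            ("ankle", "FE"): Sinusoid(amp=ankle_fe, freq=f, phase=1.8),
        },
        left_phase=0.0,
        bob_freq=f,
        bob_amp=bob,
        **kw,
    )


MOVEMENT_SCRIPTS: Dict[str, MotionScript] = {
    "A-pose": MotionScript(
        movement="A-pose",
        joints={("hip", "AB-AD"): Sinusoid(mean=-8.0, amp=0.0)},
        sway_deg=0.5, yaw_deg=0.5, bob_amp=0.003, bob_freq=0.3,
        amp_jitter=0.0,
    ),
    "gait": _gait_like("gait", 0.9, hip_fe=25.0, knee_fe=55.0,
                       ankle_fe=12.0, speed=1.2),
    "running": _gait_like("running", 1.4, hip_fe=38.0, knee_fe=75.0,
                          ankle_fe=18.0, speed=3.0, hip_aa=7.0, hip_rot=7.0,
                          knee_aa=4.0, knee_rot=6.0, bob=0.04),
    "squats": _jump_like("squats", 0.4, hip_fe=85.0, knee_fe=95.0,
                         ankle_fe=20.0, bob=-0.22),
    "j-jacks": MotionScript(
        movement="j-jacks",
        joints={
            ("hip", "AB-AD"): Sinusoid(mean=15.0, amp=14.0, freq=1.0),
            ("hip", "FE"): Sinusoid(amp=8.0, freq=1.0, phase=0.4),
            ("hip", "ROT"): Sinusoid(amp=4.0, freq=1.0, phase=0.9),
            ("knee", "FE"): Sinusoid(mean=12.0, amp=10.0, freq=1.0,
                                     phase=0.2),
            ("knee", "AB-AD"): Sinusoid(amp=2.5, freq=1.0, phase=0.5),
            ("knee", "ROT"): Sinusoid(amp=3.0, freq=1.0, phase=1.3),
            ("ankle", "FE"): Sinusoid(amp=12.0, freq=1.0, phase=1.6),
        },
        left_phase=0.0, bob_amp=0.05, bob_freq=1.0,
    ),
    "jump": _jump_like("jump", 0.8, hip_fe=70.0, knee_fe=90.0,
                       ankle_fe=25.0, bob=-0.12),
    "f-jump": _jump_like("f-jump", 0.7, hip_fe=65.0, knee_fe=85.0,
                         ankle_fe=24.0, bob=-0.10, forward_speed=0.6),
    "t-jump": _jump_like("t-jump", 0.7, hip_fe=60.0, knee_fe=80.0,
                         ankle_fe=22.0, bob=-0.10, yaw_deg=45.0,
                         yaw_freq=0.35),
}


# ---------------------------------------------------------------------------
# keypoint construction
# ---------------------------------------------------------------------------

def _default_combos() -> Dict[str, Dict[str, float]]:
    combos = {
        "nose": {"L-ASIS": 0.5, "R-ASIS": 0.5},
        "L-shoulder": {"L-ASIS": 0.6, "L-PSIS": 0.4},
        "R-shoulder": {"R-ASIS": 0.6, "R-PSIS": 0.4},
        "L-hip": {"L-ASIS": 0.5, "L-TRO": 0.3, "L-PSIS": 0.1,
                  "R-PSIS": 0.1},
        "R-hip": {"R-ASIS": 0.5, "R-TRO": 0.3, "L-PSIS": 0.1,
                  "R-PSIS": 0.1},
        "L-knee": {"L-LFE": 0.5, "L-MFE": 0.5},
        "R-knee": {"R-LFE": 0.5, "R-MFE": 0.5},
        "L-ankle": {"L-LM": 0.5, "L-MM": 0.5},
        "R-ankle": {"R-LM": 0.5, "R-MM": 0.5},
        "L-heel": {"L-CAL": 1.0},
        "R-heel": {"R-CAL": 1.0},
        "L-foot_index": {"L-TOE3": 1.0},
        "R-foot_index": {"R-TOE3": 1.0},
    }
    return combos


def _default_offsets() -> Dict[str, Tuple[str, np.ndarray]]:
    """Constant keypoint offsets (meters at reference height) expressed in
    a named segment frame."""
    return {
        "nose": ("pelvis", np.array([0.04, 0.47, 0.0])),
        "L-shoulder": ("pelvis", np.array([0.0, 0.31, -0.03])),
        "R-shoulder": ("pelvis", np.array([0.0, 0.31, 0.03])),
        "L-heel": ("foot-L", np.array([-0.005, 0.01, 0.0])),
        "R-heel": ("foot-R", np.array([-0.005, 0.01, 0.0])),
    }


@dataclass
class NoiseModel:
    """Keypoint construction map and measurement noise.

    Each keypoint is a fixed convex combination of raw landmarks plus an
    optional constant offset in a named segment frame (scaled with subject
    height), then corrupted by iid additive Gaussian noise per axis.
    ``temporal_jitter_sd`` (frames) shifts each keypoint's trajectory in
    time by a per-keypoint random offset, emulating detector latency.
    """

    keypoint_sd: float = 0.005      # m
    temporal_jitter_sd: float = 0.0  # frames
    combos: Dict[str, Dict[str, float]] = field(
        default_factory=_default_combos)
    offsets: Dict[str, Tuple[str, np.ndarray]] = field(
        default_factory=_default_offsets)

    def __post_init__(self) -> None:
        if self.keypoint_sd < 0 or self.temporal_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for name, combo in self.combos.items():
            total = sum(combo.values())
            if not np.isclose(total, 1.0):
                raise ValueError(
                    f"combination weights for {name!r} sum to {total}, "
                    "expected 1"
                )
            if any(w < 0 for w in combo.values()):
                raise ValueError(f"negative weight in combo for {name!r}")


def sample_profile(seed) -> AnthropometricProfile:
    """Draw one subject: sex ~ Bernoulli(1/2); height ~ N(1.70, 0.12^2)
    truncated to (1.40, 2.05) m; weight coupled to height with slope
    80 kg/m plus N(0, 10^2) residual, truncated positive."""
    rng = np.random.default_rng(seed)
    sex = int(rng.random() < 0.5)
    while True:
        height = rng.normal(1.70, 0.12)
        if 1.40 < height < 2.05:
            break
    while True:
        weight = 73.64 + 80.0 * (height - 1.70) + rng.normal(0.0, 10.0)
        if 20.0 < weight < 300.0:
            break
    sid = f"S{int(rng.integers(0, 10**8)):08d}"
    return AnthropometricProfile(subject_id=sid, sex_code=sex,
                                 height=height, weight=weight)


def _pelvis_pose(script: MotionScript, template: SkeletonTemplate,
                 t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Pelvis origin (T, 3) and rotation (T, 3, 3)."""
    T = len(t)
    x = script.forward_speed * t
    y = (template.pelvis_height * template.height
         + script.bob_amp * np.sin(2 * np.pi * script.bob_freq * t))
    z = np.zeros(T)
    origin = np.stack([x, y, z], axis=-1)
    yaw = script.yaw_deg * np.sin(2 * np.pi * script.yaw_freq * t)
    roll = script.sway_deg * np.sin(2 * np.pi * script.bob_freq * t + 0.3)
    tilt = script.sway_deg * np.sin(2 * np.pi * script.bob_freq * t + 0.9)
    R = np.empty((T, 3, 3))
    for i in range(T):
        cy, sy = np.cos(np.deg2rad(yaw[i])), np.sin(np.deg2rad(yaw[i]))
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        R[i] = Ry @ compose_cardan_zxy(tilt[i], roll[i], 0.0)
    return origin, R


def forward_kinematics(template: SkeletonTemplate, angles: np.ndarray,
                       pelvis_origin: np.ndarray, pelvis_rot: np.ndarray
                       ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Place the 18 raw landmarks for given joint angles and pelvis pose.

    ``angles``: (T, 3, 3, 2) degrees in the reporting convention (left-side
    AB-AD/ROT positive = adduction/internal).  Returns the (T, 18, 3)
    landmark array in :data:`~limbaug.datamodel.LANDMARKS_RAW` order and a
    dict of per-segment rotations for keypoint offsets.
    """
    T = angles.shape[0]
    pos = {name: np.empty((T, 3)) for name in LANDMARKS_RAW}
    seg_rot: Dict[str, np.ndarray] = {"pelvis": pelvis_rot}
    seg_org: Dict[str, np.ndarray] = {"pelvis": pelvis_origin}

    for name, off in template.pelvis_landmarks().items():
        pos[name] = pelvis_origin + pelvis_rot @ off

    for s, side in enumerate(SIDES):
        sign = -1.0 if side == "L" else 1.0
        hjc = (pelvis_origin
               + pelvis_rot @ template.hjc_local(side))
        R_f = np.empty((T, 3, 3))
        R_s = np.empty((T, 3, 3))
        R_ft = np.empty((T, 3, 3))
        for i in range(T):
            hip = angles[i, 0, :, s]
            knee = angles[i, 1, :, s]
            ankle = angles[i, 2, :, s]
            R_hip = compose_cardan_zxy(hip[0], sign * hip[1], sign * hip[2])
            R_knee = compose_cardan_zxy(knee[0], sign * knee[1],
                                        sign * knee[2])
            R_ankle = compose_cardan_zxy(ankle[0], 0.0, 0.0)
            R_f[i] = pelvis_rot[i] @ R_hip
            R_s[i] = R_f[i] @ R_knee
            R_ft[i] = R_s[i] @ R_ankle
        for name, off in template.femur_landmarks(side).items():
            pos[name] = hjc + R_f @ off
        knee_center = hjc + R_f @ np.array(
            [0.0, -template.thigh_length * template.height, 0.0])
        for name, off in template.shank_landmarks(side).items():
            pos[name] = knee_center + R_s @ off
        ankle_center = knee_center + R_s @ np.array(
            [0.0, -template.shank_length * template.height, 0.0])
        for name, off in template.foot_landmarks(side).items():
            pos[name] = ankle_center + R_ft @ off
        seg_rot[f"femur-{side}"] = R_f
        seg_rot[f"shank-{side}"] = R_s
        seg_rot[f"foot-{side}"] = R_ft
        seg_org[f"foot-{side}"] = ankle_center

    landmarks = np.stack([pos[name] for name in LANDMARKS_RAW], axis=1)
    return landmarks, seg_rot


def _build_keypoints(landmarks: np.ndarray, seg_rot: Dict[str, np.ndarray],
                     template: SkeletonTemplate, noise: NoiseModel,
                     rng: np.random.Generator) -> np.ndarray:
    """(T, 13, 3) keypoints in :data:`DEFAULT_KEYPOINTS` order."""
    T = landmarks.shape[0]
    index = {name: i for i, name in enumerate(LANDMARKS_RAW)}
    scale = template.height / _REF_HEIGHT
    clean = np.zeros((T, len(DEFAULT_KEYPOINTS), 3))
    for k, kp in enumerate(DEFAULT_KEYPOINTS):
        for lname, w in noise.combos[kp].items():
            clean[:, k, :] += w * landmarks[:, index[lname], :]
        if kp in noise.offsets:
            seg, off = noise.offsets[kp]
            clean[:, k, :] += seg_rot[seg] @ (np.asarray(off) * scale)
    out = clean
    if noise.temporal_jitter_sd > 0 and T > 1:
        t = np.arange(T, dtype=float)
        shifted = np.empty_like(out)
        for k in range(out.shape[1]):
            dt = rng.normal(0.0, noise.temporal_jitter_sd)
            tq = np.clip(t + dt, 0, T - 1)
            for ax in range(3):
                shifted[:, k, ax] = np.interp(tq, t, out[:, k, ax])
        out = shifted
    if noise.keypoint_sd > 0:
        out = out + rng.normal(0.0, noise.keypoint_sd, size=out.shape)
    return out


def generate_trial(profile: AnthropometricProfile, movement: str,
                   duration: float, seed,
                   noise: Optional[NoiseModel] = None,
                   script: Optional[MotionScript] = None) -> TrialRecord:
    """One paired trial with ground-truth joint angles attached.

    Landmarks are noiseless (mesh-derived ground truth); only keypoints
    carry measurement noise.
    """
    if script is None:
        if movement not in MOVEMENT_SCRIPTS:
            raise KeyError(
                f"unknown movement {movement!r}; known: {MOVEMENTS}")
        script = MOVEMENT_SCRIPTS[movement]
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    template = SkeletonTemplate(height=profile.height)
    realized = script.realize(rng) if script.amp_jitter > 0 else script
    fps = script.fps
    T = max(2, int(round(duration * fps)))
    t = np.arange(T) / fps
    angles = realized.angle_array(t)
    origin, R_p = _pelvis_pose(realized, template, t)
    landmarks, seg_rot = forward_kinematics(template, angles, origin, R_p)
    keypoints = _build_keypoints(landmarks, seg_rot, template, noise, rng)
    return TrialRecord(
        subject_id=profile.subject_id,
        profile=profile,
        keypoints=MarkerSequence(DEFAULT_KEYPOINTS, keypoints, fps,
                                 movement),
        landmarks=MarkerSequence(LANDMARKS_RAW, landmarks, fps, movement),
        true_angles=JointAngleSeries(angles, fps, movement),
    )


def generate_dataset(n_subjects: int,
                     movements: Sequence[str] = MOVEMENTS,
                     duration: float = 4.0,
                     seed: int = 0,
                     noise: Optional[NoiseModel] = None,
                     train_fraction: float = 57.0 / 71.0
                     ) -> DatasetManifest:
    """One trial per subject and movement, split by subject.

    The split ratio defaults to 57:14 training:test proportions.  All
    randomness is derived deterministically from ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_subjects)
    trials = []
    subject_ids = []
    for i, sseq in enumerate(subject_seeds):
        child = sseq.spawn(len(movements) + 1)
        profile = sample_profile(child[0])
        profile = replace_subject_id(profile, f"S{i:03d}")
        subject_ids.append(profile.subject_id)
        for j, movement in enumerate(movements):
            trials.append(generate_trial(
                profile, movement, duration, child[j + 1], noise=noise))
    n_train = int(round(train_fraction * n_subjects))
    n_train = min(max(n_train, 1), n_subjects - 1)
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(n_subjects)
    split = {}
    for rank, idx in enumerate(order):
        split[subject_ids[idx]] = "train" if rank < n_train else "test"
    return DatasetManifest(trials=trials, split=split)


def replace_subject_id(profile: AnthropometricProfile,
                       subject_id: str) -> AnthropometricProfile:
    return AnthropometricProfile(
        subject_id=subject_id, sex_code=profile.sex_code,
        height=profile.height, weight=profile.weight)
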