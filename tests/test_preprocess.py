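"""SACR substitution, centering/scaling, normalization, rotation
augmentation, feature assembly and windowing."""

import numpy as np
import pytest
from dataclasses import replace

from limbaug.datamodel import (
    DEFAULT_KEYPOINTS,
    LANDMARKS_RAW,
    AnthropometricProfile,
    MarkerSequence,
    TrialRecord,
)
from limbaug.preprocess import (
    N_FEATURES,
    N_TARGETS,
    NormalizationSpec,
    assemble_features,
    augment_rotations,
    center_and_scale,
    invert_centering,
    make_windows,
    normalize_anthropometrics,
    rotation_about_vertical,
    substitute_sacr,
)

SPEC = NormalizationSpec(height_range=(1.45, 1.95), weight_range=(40, 120))


def _landmarks(T=3, seed=0):
    rng = np.random.default_rng(seed)
    return MarkerSequence(LANDMARKS_RAW,
                          rng.normal(size=(T, len(LANDMARKS_RAW), 3)), 30.0)


class TestSacr:
    def test_midpoint(self):
        seq = _landmarks(T=1)
        pos = seq.positions.copy()
        pos[0, seq.index("R-PSIS")] = [1.0, 0.0, 0.0]
        pos[0, seq.index("L-PSIS")] = [0.0, 1.0, 0.0]
        out = substitute_sacr(seq.with_positions(pos))
        assert out.n_points == 17
        assert np.allclose(out.get("SACR")[0], [0.5, 0.5, 0.0])
        assert not out.has("L-PSIS") and not out.has("R-PSIS")

    def test_degenerate_midpoint(self):
        seq = _landmarks(T=2)
        pos = seq.positions.copy()
        p = np.array([0.3, -0.2, 0.9])
        pos[:, seq.index("R-PSIS")] = p
        pos[:, seq.index("L-PSIS")] = p
        out = substitute_sacr(seq.with_positions(pos))
        assert np.allclose(out.get("SACR"), p)

    def test_idempotent(self):
        once = substitute_sacr(_landmarks())
        twice = substitute_sacr(once)
        assert twice is once

    def test_missing_psis_named(self):
        seq = _landmarks().subset([n for n in LANDMARKS_RAW
                                   if n != "L-PSIS"])
        with pytest.raises(KeyError, match="L-PSIS"):
            substitute_sacr(seq)

    def test_other_points_untouched(self):
        seq = _landmarks()
        out = substitute_sacr(seq)
        for name in out.point_names[:-1]:
            assert np.array_equal(out.get(name), seq.get(name))


def _trial(T=4, seed=1, height=2.0):
    rng = np.random.default_rng(seed)
    profile = AnthropometricProfile("s", 1, height, 80.0)
    kp = MarkerSequence(DEFAULT_KEYPOINTS,
                        rng.normal(size=(T, 13, 3)), 30.0, "gait")
    lm = MarkerSequence(LANDMARKS_RAW,
                        rng.normal(size=(T, 18, 3)), 30.0, "gait")
    return TrialRecord(subject_id="s", profile=profile, keypoints=kp,
                       landmarks=lm)


class TestCenterScale:
    def test_hip_midpoint_is_origin(self):
        centered, _ = center_and_scale(_trial())
        mid = 0.5 * (centered.keypoints.get("L-hip")
                     + centered.keypoints.get("R-hip"))
        assert np.abs(mid).max() < 1e-12

    def test_round_trip(self):
        trial = _trial()
        centered, offsets = center_and_scale(trial)
        for orig, cent in ((trial.keypoints, centered.keypoints),
                           (trial.landmarks, centered.landmarks)):
            back = invert_centering(cent, offsets)
            assert np.allclose(back.positions, orig.positions, atol=1e-9)

    def test_height_division(self):
        trial = _trial(T=1, height=2.0)
        pos = trial.keypoints.positions.copy()
        pos[:] = 0.0  # hip midpoint at origin
        lm = trial.landmarks.positions.copy()
        lm[0, 0] = [0.0, 0.5, 0.0]
        trial = replace(trial,
                        keypoints=trial.keypoints.with_positions(pos),
                        landmarks=trial.landmarks.with_positions(lm))
        centered, _ = center_and_scale(trial)
        assert np.allclose(centered.landmarks.positions[0, 0],
                           [0.0, 0.25, 0.0])


class TestNormalization:
    @pytest.mark.parametrize("height,weight,expected", [
        (1.70, 40.0, (0.5, 0.0)),     # midpoint of range / boundary
        (1.45, 100.0, (0.0, 0.75)),   # (100-40)/80
    ])
    def test_min_max_closed_form(self, height, weight, expected):
        prof = AnthropometricProfile("s", 0, height, weight)
        h, w = normalize_anthropometrics(prof, SPEC)
        assert np.isclose(h, expected[0]) and np.isclose(w, expected[1])

    def test_extrapolation_allowed_and_logged(self, caplog):
        prof = AnthropometricProfile("s", 0, 2.10, 80.0)
        with caplog.at_level("WARNING"):
            h, _ = normalize_anthropometrics(prof, SPEC)
        assert h > 1.0
        assert "outside normalization range" in caplog.text

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="min < max"):
            NormalizationSpec(height_range=(1.9, 1.5),
                              weight_range=(40, 120))

    def test_json_round_trip(self):
        back = NormalizationSpec.from_json(SPEC.to_json())
        assert back == SPEC


class TestRotationAugmentation:
    def test_identity_angle(self):
        centered, _ = center_and_scale(_trial())
        (out,) = augment_rotations(centered, [0.0])
        assert np.allclose(out.keypoints.positions,
                           centered.keypoints.positions)

    def test_right_handed_about_vertical(self):
        R = rotation_about_vertical(90.0)
        assert np.allclose(R @ [1.0, 0.0, 0.0], [0.0, 0.0, -1.0],
                           atol=1e-12)

    def test_isometry_and_count(self):
        centered, _ = center_and_scale(_trial())
        copies = augment_rotations(centered, np.arange(8) * 45.0)
        assert len(copies) == 8
        base = centered.keypoints.positions
        d0 = np.linalg.norm(base[:, :, None] - base[:, None, :], axis=-1)
        for c in copies:
            p = c.keypoints.positions
            d = np.linalg.norm(p[:, :, None] - p[:, None, :], axis=-1)
            assert np.allclose(d, d0, atol=1e-9)

    def test_non_centered_input_rejected(self):
        with pytest.raises(ValueError, match="not hip-centered"):
            augment_rotations(_trial(), [0.0])


class TestFeatures:
    def test_shapes_and_ordering(self):
        trial = _trial()
        centered, _ = center_and_scale(
            replace(trial, landmarks=substitute_sacr(trial.landmarks)))
        X, Y = assemble_features(centered, SPEC)
        assert X.shape == (4, N_FEATURES)
        assert Y.shape == (4, N_TARGETS)
        # leading entries: sex code then normalized weight/height
        assert np.all(X[:, 0] == 1.0)
        h, w = normalize_anthropometrics(trial.profile, SPEC)
        assert np.allclose(X[:, 1], w) and np.allclose(X[:, 2], h)

    def test_identical_frames_yield_identical_features(self):
        trial = _trial(T=2)
        kp = trial.keypoints.positions.copy()
        kp[1] = kp[0]
        lm = trial.landmarks.positions.copy()
        lm[1] = lm[0]
        trial = replace(
            trial,
            keypoints=trial.keypoints.with_positions(kp),
            landmarks=substitute_sacr(
                trial.landmarks.with_positions(lm)))
        centered, _ = center_and_scale(trial)
        X, Y = assemble_features(centered, SPEC)
        assert np.array_equal(X[0], X[1]) and np.array_equal(Y[0], Y[1])

    def test_wrong_point_count_rejected(self):
        trial = _trial()
        bad = replace(trial, keypoints=trial.keypoints.subset(
            list(DEFAULT_KEYPOINTS[:10])))
        centered, _ = center_and_scale(bad)
        with pytest.raises(ValueError, match="keypoints"):
            assemble_features(centered, SPEC)


class TestWindows:
    def test_counts(self):
        X = np.zeros((20, 42))
        assert len(make_windows(X, 16, 1)) == 5
        assert len(make_windows(X[:16], 16, 1)) == 1

    def test_short_trial_padded(self):
        X = np.arange(10)[:, None] * np.ones((1, 42))
        (w,) = make_windows(X, 16, 1)
        assert w.n_padded == 6 and w.padded
        assert np.all(w.features[:7, 0] == 0)  # repeats of first frame
        assert np.all(w.features[6:, 0] == np.arange(10))

    def test_stride(self):
        X = np.zeros((20, 42))
        assert len(make_windows(X, 16, 4)) == 2

    def test_targets_follow_features(self):
        X = np.arange(20)[:, None] * np.ones((1, 42))
        Y = np.arange(20)[:, None] * np.ones((1, 51))
        windows = make_windows(X, 16, 2, Y=Y)
        for w in windows:
            assert np.all(w.targets[:, 0] == w.features[:, 0])
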