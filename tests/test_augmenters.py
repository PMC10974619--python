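"""Augmenter model contracts: shapes, determinism, persistence,
prediction plumbing.  (Training quality is exercised in the acceptance
suite; here training runs are kept to a few epochs.)"""

import numpy as np
import pytest

from limbaug import nn
from limbaug.augmenters import (
    AugmenterResults,
    AugmenterSpec,
    MarkerAugmenter,
    TrainingConfig,
    build_network,
    load_results,
)
from limbaug.datamodel import DatasetManifest
from limbaug.preprocess import N_FEATURES, N_TARGETS, NormalizationSpec
from limbaug.synthetic import generate_dataset, generate_trial

NORM = NormalizationSpec(height_range=(1.5, 1.9), weight_range=(50, 100))


def _untrained_results(spec, seed=0):
    net = build_network(spec, seed)
    return AugmenterResults(spec=spec, state=net.state_dict(),
                            normalization=NORM, training_log=[], seed=seed)


class TestSpecs:
    def test_defaults_match_published_architectures(self):
        mlp = AugmenterSpec.mlp()
        assert mlp.mlp_blocks == ((256, "tanh"), (128, "relu"),
                                  (224, "relu"))
        lstm = AugmenterSpec.lstm()
        assert (lstm.lstm_layers, lstm.lstm_units, lstm.window) == (2, 128,
                                                                    16)
        tfm = AugmenterSpec.transformer()
        assert (tfm.num_layers, tfm.num_heads, tfm.hidden_dim) == (6, 14,
                                                                   224)

    def test_head_divisibility_checked(self):
        with pytest.raises(ValueError, match="divisible"):
            AugmenterSpec(architecture="transformer", num_heads=15)

    def test_io_contract_is_fixed(self):
        with pytest.raises(ValueError, match="42"):
            AugmenterSpec(architecture="mlp", input_dim=40)

    def test_training_defaults_follow_published_recipes(self):
        mlp = TrainingConfig.default_for("mlp")
        assert (mlp.learning_rate, mlp.optimizer, mlp.epochs,
                mlp.batch_size) == (2e-5, "rmsprop", 100, 64)
        lstm = TrainingConfig.default_for("lstm")
        assert (lstm.learning_rate, lstm.optimizer, lstm.epochs,
                lstm.batch_size) == (7e-5, "adam", 200, 32)
        tfm = TrainingConfig.default_for("transformer")
        assert (tfm.learning_rate, tfm.optimizer, tfm.epochs,
                tfm.batch_size) == (7e-5, "adam", 300, 64)


class TestNetworks:
    @pytest.mark.parametrize("arch", ["mlp", "lstm", "transformer"])
    def test_output_arity_51(self, arch, rng):
        spec = AugmenterSpec.reduced(arch)
        net = build_network(spec, 3)
        if arch == "mlp":
            x = rng.normal(size=(7, N_FEATURES))
            assert net(nn.Tensor(x)).shape == (7, N_TARGETS)
        else:
            x = rng.normal(size=(2, spec.window, N_FEATURES))
            assert net(nn.Tensor(x)).shape == (2, spec.window, N_TARGETS)

    def test_mlp_block_structure(self):
        net = build_network(AugmenterSpec.mlp(), 0)
        assert net._children["dense0"].W.shape == (42, 256)
        assert net._children["dense1"].W.shape == (256, 128)
        assert net._children["dense2"].W.shape == (128, 224)
        assert net._children["head"].W.shape == (224, 51)
        assert "bn2" in net._children

    @pytest.mark.parametrize("layout", ["frame", "frame-axis"])
    def test_transformer_layouts_share_contract(self, layout, rng):
        spec = AugmenterSpec(architecture="transformer", hidden_dim=16,
                             num_layers=1, num_heads=2, ffn_dim=32,
                             token_layout=layout)
        net = build_network(spec, 0)
        x = rng.normal(size=(3, 16, N_FEATURES))
        assert net(nn.Tensor(x)).shape == (3, 16, N_TARGETS)

    @pytest.mark.parametrize("arch", ["mlp", "lstm", "transformer"])
    def test_seeded_build_is_deterministic(self, arch, rng):
        spec = AugmenterSpec.reduced(arch)
        x = rng.normal(size=(2, N_FEATURES) if arch == "mlp"
                       else (2, spec.window, N_FEATURES))
        a = build_network(spec, 11)
        b = build_network(spec, 11)
        assert np.array_equal(a(nn.Tensor(x)).data, b(nn.Tensor(x)).data)
        c = build_network(spec, 12)
        assert not np.array_equal(a(nn.Tensor(x)).data,
                                  c(nn.Tensor(x)).data)


@pytest.fixture(scope="module")
def tiny_manifest():
    return generate_dataset(3, ("gait",), 1.0, seed=202)


class TestTraining:
    def test_seeded_training_reproducible(self, tiny_manifest):
        model = MarkerAugmenter.from_manifest(tiny_manifest, "mlp")
        cfg = TrainingConfig(learning_rate=1e-3, optimizer="rmsprop",
                             epochs=3, batch_size=32)
        a = model.fit(cfg, seed=5)
        b = model.fit(cfg, seed=5)
        assert a.training_log == b.training_log
        for k in a.state:
            assert np.array_equal(a.state[k], b.state[k]), k

    def test_empty_training_set_rejected(self, tiny_manifest):
        empty = DatasetManifest(
            trials=tiny_manifest.trials,
            split={s: "test" for s in tiny_manifest.subjects})
        with pytest.raises(ValueError, match="training"):
            MarkerAugmenter.from_manifest(empty, "mlp")

    def test_unsupervised_training_trial_rejected(self, tiny_manifest):
        from dataclasses import replace
        trials = [replace(t, landmarks=None, true_angles=None)
                  for t in tiny_manifest.trials]
        man = DatasetManifest(trials=trials, split=tiny_manifest.split)
        with pytest.raises(ValueError, match="landmarks"):
            MarkerAugmenter.from_manifest(man, "mlp")

    def test_loss_decreases_on_short_run(self, tiny_manifest):
        model = MarkerAugmenter.from_manifest(tiny_manifest, "mlp")
        res = model.fit(TrainingConfig(learning_rate=1e-3,
                                       optimizer="rmsprop", epochs=5,
                                       batch_size=64), seed=0)
        assert res.training_log[-1] < res.training_log[0]

    def test_rotation_augmentation_multiplies_data(self, tiny_manifest):
        plain = MarkerAugmenter.from_manifest(tiny_manifest, "mlp")
        aug = MarkerAugmenter.from_manifest(
            tiny_manifest, "mlp", augmentation_angles=(0.0, 120.0, 240.0))
        assert len(aug.trial_features) == 3 * len(plain.trial_features)


class TestPrediction:
    @pytest.mark.parametrize("arch", ["mlp", "lstm", "transformer"])
    def test_output_names_frames_and_units(self, arch, profile):
        trial = generate_trial(profile, "gait", 1.0, seed=3)
        spec = AugmenterSpec.reduced(arch)
        res = _untrained_results(spec)
        pred = res.predict_trial(trial.keypoints, profile)
        assert pred.n_points == 17
        assert pred.n_frames == trial.keypoints.n_frames
        assert pred.fps == trial.keypoints.fps
        # world frame: the inverse hip-centering places outputs within a
        # few body heights of the subject even for untrained weights
        hips = 0.5 * (trial.keypoints.get("L-hip")
                      + trial.keypoints.get("R-hip"))
        d = np.linalg.norm(pred.positions - hips[:, None, :], axis=-1)
        assert np.isfinite(d).all()
        assert d.max() < 20.0 * profile.height

    @pytest.mark.parametrize("arch", ["lstm", "transformer"])
    def test_short_trial_padding_contract(self, arch, profile):
        trial = generate_trial(profile, "gait", 5 / 60.0, seed=3)
        assert trial.keypoints.n_frames == 5
        res = _untrained_results(AugmenterSpec.reduced(arch))
        pred = res.predict_trial(trial.keypoints, profile)
        assert pred.n_frames == 5

    def test_missing_keypoint_rejected(self, profile):
        trial = generate_trial(profile, "gait", 1.0, seed=3)
        res = _untrained_results(AugmenterSpec.reduced("mlp"))
        partial = trial.keypoints.subset(
            [n for n in trial.keypoints.point_names if n != "L-hip"])
        with pytest.raises(KeyError, match="L-hip"):
            res.predict_trial(partial, profile)


class TestPersistence:
    @pytest.mark.parametrize("arch", ["mlp", "lstm", "transformer"])
    def test_checkpoint_round_trip_preserves_predictions(
            self, arch, tmp_path, profile):
        trial = generate_trial(profile, "gait", 0.5, seed=8)
        res = _untrained_results(AugmenterSpec.reduced(arch), seed=4)
        path = tmp_path / f"{arch}.npz"
        res.save(path)
        back = load_results(path)
        assert back.spec == res.spec
        assert back.normalization == res.normalization
        a = res.predict_trial(trial.keypoints, profile)
        b = back.predict_trial(trial.keypoints, profile)
        np.testing.assert_allclose(b.positions, a.positions, rtol=1e-6)

    def test_corrupted_checkpoint_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"this is not a checkpoint")
        with pytest.raises(ValueError, match="corrupt"):
            load_results(path)

    def test_version_mismatch_rejected(self, tmp_path, monkeypatch):
        res = _untrained_results(AugmenterSpec.reduced("mlp"))
        path = tmp_path / "m.npz"
        import limbaug.augmenters as aug
        monkeypatch.setattr(aug, "CHECKPOINT_VERSION", 99)
        res.save(path)
        monkeypatch.undo()
        with pytest.raises(ValueError, match="version"):
            load_results(path)

    def test_summary_mentions_architecture_and_ranges(self):
        res = _untrained_results(AugmenterSpec.reduced("lstm"))
        text = res.summary()
        assert "lstm" in text
        assert "height range" in text
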