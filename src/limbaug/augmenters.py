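"""Marker-augmentation models: MLP, LSTM and Transformer.

Organized as model/results pairs: :class:`MarkerAugmenter` is built from
preprocessed training data (or directly from a
:class:`~limbaug.datamodel.DatasetManifest`), its :meth:`~MarkerAugmenter.fit`
trains the network and returns an :class:`AugmenterResults` carrying the
learned weights, the per-epoch loss history, the normalization spec and
prediction/persistence methods.

All three architectures share the 42-input / 51-output contract: inputs are
``[sex, weight_norm, height_norm]`` plus the 13 hip-centered, height-scaled
keypoints; outputs are the 17 processed landmarks in the same scaled frame.
The MLP maps single frames; the LSTM and Transformer map 16-frame windows
sequence-to-sequence, and inference stitches stride-1 windows by averaging
the overlapping per-frame predictions.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .datamodel import (
    KEYPOINT_FEATURE_ORDER,
    AnthropometricProfile,
    DatasetManifest,
    MarkerSequence,
    TrialRecord,
)
from .preprocess import (
    N_FEATURES,
    N_TARGETS,
    NormalizationSpec,
    assemble_features,
    augment_rotations,
    center_and_scale,
    features_to_landmarks,
    invert_centering,
    make_windows,
    substitute_sacr,
)

__all__ = [
    "AugmenterSpec",
    "TrainingConfig",
    "MarkerAugmenter",
    "AugmenterResults",
    "build_network",
    "load_results",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1

ARCHITECTURES = ("mlp", "lstm", "transformer")


@dataclass(frozen=True)
class AugmenterSpec:
    """Architecture hyperparameters.

    Defaults reproduce the published architectures: a 3-block MLP
    (256 tanh / 128 relu / 224 relu, each dense -> batchnorm -> activation),
    a 2-layer 128-unit LSTM over 16-frame windows, and a 6-layer 14-head
    Transformer encoder with hidden width 224 (= 14 heads x 16).
    """

    architecture: str
    input_dim: int = N_FEATURES
    output_dim: int = N_TARGETS
    mlp_blocks: Tuple[Tuple[int, str], ...] = (
        (256, "tanh"), (128, "relu"), (224, "relu"))
    lstm_layers: int = 2
    lstm_units: int = 128
    window: int = 16
    hidden_dim: int = 224
    num_layers: int = 6
    num_heads: int = 14
    ffn_dim: Optional[int] = None
    #: "frame": one token per frame (default); "frame-axis": 16 keypoint+
    #: anthropometric channels projected pointwise, one token per
    #: (frame, coordinate-axis) pair.
    token_layout: str = "frame"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}")
        if self.input_dim != N_FEATURES or self.output_dim != N_TARGETS:
            raise ValueError(
                f"the model contract is fixed at {N_FEATURES} inputs and "
                f"{N_TARGETS} outputs")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.architecture == "transformer" and (
                self.hidden_dim % self.num_heads != 0):
            raise ValueError(
                f"hidden_dim {self.hidden_dim} must be divisible by "
                f"num_heads {self.num_heads}")
        if self.token_layout not in ("frame", "frame-axis"):
            raise ValueError(
                f"unknown token_layout {self.token_layout!r}")

    @classmethod
    def mlp(cls) -> "AugmenterSpec":
        return cls(architecture="mlp")

    @classmethod
    def lstm(cls) -> "AugmenterSpec":
        return cls(architecture="lstm")

    @classmethod
    def transformer(cls) -> "AugmenterSpec":
        return cls(architecture="transformer")

    @classmethod
    def reduced(cls, architecture: str) -> "AugmenterSpec":
        """Width-reduced variants for desk-scale experiments."""
        if architecture == "mlp":
            return cls.mlp()
        if architecture == "lstm":
            return cls(architecture="lstm", lstm_units=32)
        if architecture == "transformer":
            return cls(architecture="transformer", hidden_dim=32,
                       num_layers=2, num_heads=4, ffn_dim=64)
        raise ValueError(f"unknown architecture {architecture!r}")

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "input_dim": self.input_dim,
            "output_dim": self.output_dim,
            "mlp_blocks": [list(b) for b in self.mlp_blocks],
            "lstm_layers": self.lstm_layers,
            "lstm_units": self.lstm_units,
            "window": self.window,
            "hidden_dim": self.hidden_dim,
            "num_layers": self.num_layers,
            "num_heads": self.num_heads,
            "ffn_dim": self.ffn_dim,
            "token_layout": self.token_layout,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AugmenterSpec":
        d = dict(d)
        d["mlp_blocks"] = tuple(tuple(b) for b in d["mlp_blocks"])
        return cls(**d)

    @property
    def sequential(self) -> bool:
        return self.architecture in ("lstm", "transformer")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; defaults per architecture follow the
    published training recipes (RMSprop 2e-5 / 100 epochs / batch 64 for
    the MLP; Adam 7e-5 with 200 epochs / batch 32 for the LSTM and
    300 epochs / batch 64 for the Transformer; MSE loss throughout)."""

    learning_rate: float
    optimizer: str
    epochs: int
    batch_size: int
    loss: str = "mse"
    window_stride: int = 1
    #: multiplicative per-epoch learning-rate decay (1 = constant).
    lr_decay: float = 1.0
    #: epochs over which the learning rate ramps linearly from lr/n to lr.
    warmup_epochs: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.window_stride < 1:
            raise ValueError("batch_size and window_stride must be >= 1")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is supported")

    @classmethod
    def default_for(cls, architecture: str) -> "TrainingConfig":
        if architecture == "mlp":
            return cls(learning_rate=2e-5, optimizer="rmsprop", epochs=100,
                       batch_size=64)
        if architecture == "lstm":
            return cls(learning_rate=7e-5, optimizer="adam", epochs=200,
                       batch_size=32)
        if architecture == "transformer":
            return cls(learning_rate=7e-5, optimizer="adam", epochs=300,
                       batch_size=64)
        raise ValueError(f"unknown architecture {architecture!r}")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "optimizer": self.optimizer,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "loss": self.loss,
            "window_stride": self.window_stride,
            "lr_decay": self.lr_decay,
            "warmup_epochs": self.warmup_epochs,
        }


#: Desk-scale training configurations for the synthetic-recovery
#: experiments (tens of subjects, tens of thousands of frames).  Epoch
#: counts are reduced relative to the published recipes (100 / 30 / 30),
#: and the learning-rate schedules are rescaled accordingly: the published
#: rates were chosen for a dataset more than an order of magnitude larger,
#: where one epoch takes many more optimizer steps.
SCALED_TRAINING = {
    "mlp": TrainingConfig(learning_rate=2e-3, optimizer="rmsprop",
                          epochs=100, batch_size=64, lr_decay=0.94),
    "lstm": TrainingConfig(learning_rate=2e-3, optimizer="adam",
                           epochs=30, batch_size=32, lr_decay=0.9,
                           window_stride=2),
    "transformer": TrainingConfig(learning_rate=8e-3, optimizer="adam",
                                  epochs=30, batch_size=64, lr_decay=0.93,
                                  warmup_epochs=2, window_stride=1),
}


# ---------------------------------------------------------------------------
# network definitions
# ---------------------------------------------------------------------------

_ACTIVATIONS = {"tanh": lambda t: t.tanh(), "relu": lambda t: t.relu()}


class _MLPNet(nn.Module):
    """dense -> batchnorm -> activation blocks, then a linear head."""

    def __init__(self, spec: AugmenterSpec, rng: np.random.Generator):
        super().__init__()
        dim = spec.input_dim
        self.acts = []
        for i, (units, act) in enumerate(spec.mlp_blocks):
            self.add_module(f"dense{i}", nn.Dense(dim, units, rng))
            self.add_module(f"bn{i}", nn.BatchNorm(units))
            self.acts.append(_ACTIVATIONS[act])
            dim = units
        self.add_module("head", nn.Dense(dim, spec.output_dim, rng))
        self.n_blocks = len(spec.mlp_blocks)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for i in range(self.n_blocks):
            x = self._children[f"dense{i}"](x)
            x = self._children[f"bn{i}"](x)
            x = self.acts[i](x)
        return self._children["head"](x)


class _LSTMNet(nn.Module):
    """Stacked LSTM layers with a per-frame linear head
    (sequence-to-sequence over the training window)."""

    def __init__(self, spec: AugmenterSpec, rng: np.random.Generator):
        super().__init__()
        dim = spec.input_dim
        self.n_layers = spec.lstm_layers
        for i in range(spec.lstm_layers):
            self.add_module(f"lstm{i}", nn.LSTMLayer(dim, spec.lstm_units,
                                                     rng))
            dim = spec.lstm_units
        self.add_module("head", nn.Dense(dim, spec.output_dim, rng))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for i in range(self.n_layers):
            x = self._children[f"lstm{i}"](x)
        return self._children["head"](x)


class _TransformerNet(nn.Module):
    """Self-attention encoder over a window of frames.

    Two token layouts are supported (``spec.token_layout``):

    * ``"frame"`` (default) — one token per frame: the 42 per-frame
      features are projected linearly to the hidden width, so the encoder
      attends over time like the LSTM does.
    * ``"frame-axis"`` — the window is viewed as 13 keypoint channels plus
      3 anthropometric pseudo-channels (each scalar replicated across the
      X/Y/Z slots), giving a (B, W, 3, 16) tensor; a pointwise (1x1)
      projection maps the 16 channels to the hidden width and the W x 3
      flattened (frame, coordinate-axis) pairs become the token sequence.

    In both layouts a sine positional embedding is added to the
    sqrt(hidden)-scaled embeddings, the tokens run through ``num_layers``
    post-norm self-attention blocks (attention + residual + layernorm,
    feed-forward + residual + layernorm), and a linear head emits the 51
    landmark coordinates per frame.
    """

    def __init__(self, spec: AugmenterSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        H = spec.hidden_dim
        W = spec.window
        ffn = spec.ffn_dim or 2 * H
        if spec.token_layout == "frame":
            self.n_tokens = W
            self.add_module("proj", nn.Dense(spec.input_dim, H, rng))
            self.add_module("head", nn.Dense(H, spec.output_dim, rng))
        else:
            n_channels = 3 + (spec.input_dim - 3) // 3  # 16
            self.n_tokens = W * 3
            self.add_module("proj", nn.Dense(n_channels, H, rng))
            self.add_module("head", nn.Dense(3 * H, spec.output_dim, rng))
        self.posenc = nn.sine_positional_encoding(self.n_tokens, H)
        for i in range(spec.num_layers):
            self.add_module(f"attn{i}",
                            nn.MultiHeadAttention(H, spec.num_heads, rng))
            self.add_module(f"ln{i}a", nn.LayerNorm(H))
            self.add_module(f"ffn{i}a", nn.Dense(H, ffn, rng))
            self.add_module(f"ffn{i}b", nn.Dense(ffn, H, rng))
            self.add_module(f"ln{i}b", nn.LayerNorm(H))

    def _tokens(self, x: nn.Tensor) -> nn.Tensor:
        B, W, F = x.shape
        H = self.spec.hidden_dim
        if self.spec.token_layout == "frame":
            h = self._children["proj"](x)           # (B, W, H)
        else:
            anthro = x[:, :, 0:3]                   # (B, W, 3)
            coords = x[:, :, 3:].reshape(B, W, (F - 3) // 3, 3)
            # anthropometric pseudo-channels: replicate over X/Y/Z slots
            a3 = anthro.reshape(B, W, 3, 1) * np.ones((1, 1, 1, 3))
            chan = nn.concat([a3, coords], axis=2)  # (B, W, 16, 3)
            tokens = chan.transpose(0, 1, 3, 2)     # (B, W, 3, 16)
            h = self._children["proj"](tokens).reshape(B, self.n_tokens, H)
        # sqrt(H) scaling keeps the content dominant over the additive
        # positional signal (standard transformer practice)
        return h * np.sqrt(H) + self.posenc

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        B, W, _ = x.shape
        H = self.spec.hidden_dim
        h = self._tokens(x)
        for i in range(self.spec.num_layers):
            a = self._children[f"attn{i}"](h)
            h = self._children[f"ln{i}a"](h + a)
            f = self._children[f"ffn{i}b"](
                self._children[f"ffn{i}a"](h).relu())
            h = self._children[f"ln{i}b"](h + f)
        if self.spec.token_layout == "frame":
            return self._children["head"](h)
        per_frame = h.reshape(B, W, 3 * H)
        return self._children["head"](per_frame)


def build_network(spec: AugmenterSpec, seed: int) -> nn.Module:
    """Seeded, reproducible network construction."""
    rng = np.random.default_rng(seed)
    if spec.architecture == "mlp":
        return _MLPNet(spec, rng)
    if spec.architecture == "lstm":
        return _LSTMNet(spec, rng)
    return _TransformerNet(spec, rng)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

def _preprocess_trial(trial: TrialRecord,
                      spec: NormalizationSpec,
                      augmentation_angles: Optional[Sequence[float]] = None,
                      ) -> List[Tuple[np.ndarray, Optional[np.ndarray]]]:
    """Center, scale and (optionally) rotation-augment one trial.

    Returns one (features, targets) pair per augmentation angle (a single
    pair when no augmentation is requested).
    """
    work = trial
    if work.landmarks is not None:
        work = replace(work, landmarks=substitute_sacr(work.landmarks))
    centered, _ = center_and_scale(work)
    if augmentation_angles is None:
        return [assemble_features(centered, spec)]
    copies = augment_rotations(centered, augmentation_angles)
    return [assemble_features(c, spec) for c in copies]


class MarkerAugmenter:
    """Keypoint-to-landmark augmentation model.

    Parameters
    ----------
    trial_features, trial_targets : lists of arrays
        Per-trial (T, 42) inputs and (T, 51) targets, already hip-centered,
        height-scaled and min-max normalized.
    spec : AugmenterSpec
    normalization : NormalizationSpec
        The anthropometric ranges the features were built with; stored in
        the results so inference reuses them.
    """

    def __init__(self, trial_features: Sequence[np.ndarray],
                 trial_targets: Sequence[np.ndarray],
                 spec: AugmenterSpec,
                 normalization: NormalizationSpec):
        if len(trial_features) == 0:
            raise ValueError("empty training set")
        if len(trial_features) != len(trial_targets):
            raise ValueError("feature/target trial count mismatch")
        for X, Y in zip(trial_features, trial_targets):
            if Y is None:
                raise ValueError("all training trials must be supervised")
            if X.shape[1] != spec.input_dim or Y.shape[1] != spec.output_dim:
                raise ValueError("feature/target dimensions do not match "
                                 "the model contract")
        self.trial_features = [np.asarray(X, dtype=float)
                               for X in trial_features]
        self.trial_targets = [np.asarray(Y, dtype=float)
                              for Y in trial_targets]
        self.spec = spec
        self.normalization = normalization

    @classmethod
    def from_manifest(cls, manifest: DatasetManifest,
                      architecture: str = "mlp",
                      spec: Optional[AugmenterSpec] = None,
                      normalization: Optional[NormalizationSpec] = None,
                      augmentation_angles: Optional[Sequence[float]] = None,
                      ) -> "MarkerAugmenter":
        """Build the model from a manifest's training split.

        The normalization ranges default to the training subjects' ranges.
        ``augmentation_angles`` (degrees) adds rotated copies of every
        training trial about the vertical axis.
        """
        spec = spec or AugmenterSpec(architecture=architecture)
        trials = manifest.train_trials
        if not trials:
            raise ValueError("manifest has no training trials")
        if normalization is None:
            profiles = {t.subject_id: t.profile for t in trials}
            normalization = NormalizationSpec.from_profiles(
                profiles.values())
        feats, targs = [], []
        for trial in trials:
            if trial.landmarks is None:
                raise ValueError(
                    f"training trial of subject {trial.subject_id!r} has "
                    "no landmarks")
            for X, Y in _preprocess_trial(trial, normalization,
                                          augmentation_angles):
                feats.append(X)
                targs.append(Y)
        return cls(feats, targs, spec, normalization)

    # -- training ----------------------------------------------------------
    def _training_arrays(self, config: TrainingConfig
                         ) -> Tuple[np.ndarray, np.ndarray]:
        if not self.spec.sequential:
            X = np.concatenate(self.trial_features, axis=0)
            Y = np.concatenate(self.trial_targets, axis=0)
            return X, Y
        xs, ys = [], []
        for X, Y in zip(self.trial_features, self.trial_targets):
            for w in make_windows(X, self.spec.window,
                                  stride=config.window_stride, Y=Y):
                xs.append(w.features)
                ys.append(w.targets)
        return np.stack(xs), np.stack(ys)

    def fit(self, config: Optional[TrainingConfig] = None,
            seed: int = 0) -> "AugmenterResults":
        """Train with minibatch gradient descent on the MSE loss.

        Fully deterministic given ``seed`` (initialization and batch
        shuffling both derive from it).
        """
        config = config or TrainingConfig.default_for(self.spec.architecture)
        net = build_network(self.spec, seed)
        X, Y = self._training_arrays(config)
        n = X.shape[0]
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0x5EED]))
        opt = nn.make_optimizer(config.optimizer, net.parameters(),
                                config.learning_rate)
        history = []
        net.train()
        for epoch in range(config.epochs):
            warm = 1.0
            if config.warmup_epochs > 0:
                warm = min(1.0, (epoch + 1) / (config.warmup_epochs + 1))
            opt.lr = config.learning_rate * warm * config.lr_decay ** epoch
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                xb = nn.Tensor(X[idx])
                yb = Y[idx]
                pred = net(xb)
                diff = pred - nn.Tensor(yb)
                loss = (diff * diff).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch "
                        f"{start // config.batch_size} "
                        f"(indices {idx[:5]}...)")
                net.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        if history[-1] >= history[0] and config.epochs > 1:
            warnings.warn(
                "training loss did not decrease "
                f"({history[0]:.3e} -> {history[-1]:.3e})",
                RuntimeWarning, stacklevel=2)
        return AugmenterResults(
            spec=self.spec, state=net.state_dict(),
            normalization=self.normalization,
            training_log=history, seed=seed, config=config)


@dataclass
class AugmenterResults:
    """A trained augmenter: weights, normalization and training history."""

    spec: AugmenterSpec
    state: Dict[str, np.ndarray]
    normalization: NormalizationSpec
    training_log: List[float]
    seed: int
    config: Optional[TrainingConfig] = None

    def _network(self) -> nn.Module:
        net = build_network(self.spec, self.seed)
        net.load_state_dict(self.state)
        net.eval()
        return net

    # -- prediction --------------------------------------------------------
    def predict_frames(self, X: np.ndarray, batch: int = 4096) -> np.ndarray:
        """Raw forward pass: (T, 42) scaled features -> (T, 51) scaled
        landmark coordinates, with window stitching for sequence models."""
        X = np.asarray(X, dtype=float)
        net = self._network()
        if not self.spec.sequential:
            out = np.empty((X.shape[0], self.spec.output_dim))
            for start in range(0, X.shape[0], batch):
                sl = slice(start, start + batch)
                out[sl] = net(nn.Tensor(X[sl])).data
            return out
        W = self.spec.window
        T = X.shape[0]
        windows = make_windows(X, W, stride=1)
        acc = np.zeros((T, self.spec.output_dim))
        count = np.zeros(T)
        batch_w = max(1, batch // W)
        for start in range(0, len(windows), batch_w):
            chunk = windows[start:start + batch_w]
            xb = np.stack([w.features for w in chunk])
            pred = net(nn.Tensor(xb)).data
            for w, p in zip(chunk, pred):
                real = p[w.n_padded:]
                frames = np.arange(w.start, w.start + real.shape[0])
                acc[frames] += real
                count[frames] += 1
            del pred
        return acc / count[:, None]

    def predict_trial(self, keypoints: MarkerSequence,
                      profile: AnthropometricProfile) -> MarkerSequence:
        """World-frame landmark prediction for one trial.

        Applies the stored normalization, runs the network, then inverts
        the height scaling and hip centering, so the output is a 17-point
        sequence in meters with the input's frame count and rate.
        """
        missing = set(KEYPOINT_FEATURE_ORDER) - set(keypoints.point_names)
        if missing:
            raise KeyError(f"missing keypoints: {sorted(missing)}")
        trial = TrialRecord(subject_id=profile.subject_id, profile=profile,
                            keypoints=keypoints)
        centered, offsets = center_and_scale(trial)
        X, _ = assemble_features(centered, self.normalization)
        Y = self.predict_frames(X)
        scaled = features_to_landmarks(Y, keypoints.fps, keypoints.movement)
        return invert_centering(scaled, offsets)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: spec + normalization + weights + log."""
        meta = {
            "version": CHECKPOINT_VERSION,
            "spec": self.spec.to_dict(),
            "normalization": self.normalization.to_json(),
            "training_log": self.training_log,
            "seed": self.seed,
            "config": self.config.to_dict() if self.config else None,
        }
        arrays = {f"w::{k}": v for k, v in self.state.items()}
        arrays["meta"] = np.array(json.dumps(meta))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "AugmenterResults":
        try:
            with np.load(path, allow_pickle=False) as data:
                if "meta" not in data:
                    raise ValueError(f"{path}: not an augmenter checkpoint")
                meta = json.loads(str(data["meta"]))
                state = {k[3:]: data[k] for k in data.files
                         if k.startswith("w::")}
        except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
            raise ValueError(f"{path}: corrupted checkpoint") from exc
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"{path}: checkpoint version {meta.get('version')} "
                f"unsupported (expected {CHECKPOINT_VERSION})")
        config = None
        if meta.get("config"):
            config = TrainingConfig(**meta["config"])
        return cls(
            spec=AugmenterSpec.from_dict(meta["spec"]),
            state=state,
            normalization=NormalizationSpec.from_json(meta["normalization"]),
            training_log=list(meta["training_log"]),
            seed=int(meta["seed"]),
            config=config,
        )

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.state.values()))

    def summary(self) -> str:
        lines = [
            "Marker augmentation model",
            "=" * 42,
            f"architecture:     {self.spec.architecture}",
            f"parameters:       {self.n_parameters}",
            f"inputs/outputs:   {self.spec.input_dim} -> "
            f"{self.spec.output_dim}",
            f"epochs trained:   {len(self.training_log)}",
        ]
        if self.training_log:
            lines.append(f"initial loss:     {self.training_log[0]:.6g}")
            lines.append(f"final loss:       {self.training_log[-1]:.6g}")
        hr = self.normalization.height_range
        wr = self.normalization.weight_range
        lines.append(f"height range (m): ({hr[0]:.3f}, {hr[1]:.3f})")
        lines.append(f"weight range (kg): ({wr[0]:.2f}, {wr[1]:.2f})")
        lines.append(f"seed:             {self.seed}")
        return "\n".join(lines)


def load_results(path) -> AugmenterResults:
    """Module-level alias for :meth:`AugmenterResults.load`."""
    return AugmenterResults.load(path)
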