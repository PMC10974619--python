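"""Neural-network layers built on the autodiff engine.

Initialization follows the common Glorot-uniform scheme; batch
normalization uses running statistics for inference (momentum 0.99,
epsilon 1e-3, the Keras defaults).
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Module", "Dense", "BatchNorm", "LayerNorm", "LSTMLayer",
           "MultiHeadAttention", "sine_positional_encoding"]


class Module:
    """Base class: parameter registry and train/eval mode."""

    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self._children: Dict[str, "Module"] = {}
        self.training = True

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out = {prefix + name: t for name, t in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {name: t.data.copy()
               for name, t in self.named_parameters().items()}
        for name, buf in self.named_buffers().items():
            out[name] = buf.copy()
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self.named_buffers()
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {value.shape}")
                params[name].data = np.array(value, dtype=float)
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected parameter {name!r}")
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")

    def named_buffers(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out = dict(getattr(self, "_buffers", {}))
        out = {prefix + k: v for k, v in out.items()}
        for cname, child in self._children.items():
            out.update(child.named_buffers(prefix + cname + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Dense(Module):
    """Affine map on the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = self.add_param("W", _glorot(rng, in_dim, out_dim))
        self.b = self.add_param("b", np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class BatchNorm(Module):
    """Batch normalization over all axes but the last.

    Keras-style defaults: momentum 0.99 on the running statistics,
    epsilon 1e-3.
    """

    def __init__(self, dim: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self._buffers = {
            "running_mean": np.zeros(dim),
            "running_var": np.ones(dim),
        }

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self._buffers["running_mean"] *= m
            self._buffers["running_mean"] += (1 - m) * mu
            self._buffers["running_var"] *= m
            self._buffers["running_var"] += (1 - m) * var
            mean_t = x.mean(axis=axes, keepdims=True)
            centered = x - mean_t
            var_t = (centered * centered).mean(axis=axes, keepdims=True)
            norm = centered / ((var_t + self.eps) ** 0.5)
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
            norm = (x - mu) / np.sqrt(var + self.eps)
        return norm * self.gamma + self.beta


class LayerNorm(Module):
    """Normalization over the last axis (transformer blocks)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class LSTMLayer(Module):
    """Standard LSTM over a (B, T, F) sequence, returning (B, T, H).

    Gate order i, f, g, o; the forget-gate bias starts at 1.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.Wx = self.add_param("Wx", _glorot(rng, in_dim, 4 * hidden))
        self.Wh = self.add_param("Wh", _glorot(rng, hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = self.add_param("b", b)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        # input projection for every timestep in one matmul
        zx = x @ self.Wx + self.b
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            z = zx[:, t, :] + h @ self.Wh
            i = z[:, 0:H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(B, 1, H))
        return concat(outs, axis=1)


def sine_positional_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Classic sine/cosine positional embedding table, shape (n, dim)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with ``heads`` heads."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(
                f"hidden dim {dim} not divisible by {heads} heads")
        self.dim = dim
        self.heads = heads
        self.dh = dim // heads
        self.q = self.add_module("q", Dense(dim, dim, rng))
        self.k = self.add_module("k", Dense(dim, dim, rng))
        self.v = self.add_module("v", Dense(dim, dim, rng))
        self.out = self.add_module("out", Dense(dim, dim, rng))

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.heads, self.dh).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        q = self._split(self.q(x), B, T)
        k = self._split(self.k(x), B, T)
        v = self._split(self.v(x), B, T)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, self.dim)
        return self.out(merged)
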