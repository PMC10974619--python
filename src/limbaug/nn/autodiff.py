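"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the augmentation networks need: broadcasted
arithmetic, (batched) matrix products, the usual activations, reductions,
reshapes and concatenation.  Gradients are accumulated by a topological
backward sweep from a scalar loss.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "stack", "DTYPE"]

#: Computation dtype.  Single precision: the networks are trained with
#: stochastic gradient descent where float32 is ample, and it halves the
#: memory traffic of the numpy kernels.
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1
                 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared")
    __array_priority__ = 100  # numpy defers to our operators

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self._grad_shared = False

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, grad: np.ndarray) -> None:
        # First contribution is adopted without copying; the array may be
        # shared with a sibling, so a second contribution allocates a
        # fresh sum instead of mutating in place.
        if self.grad is None:
            self.grad = grad
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + grad
            self._grad_shared = False
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / other.data ** 2, other.shape))
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = backward
        return out

    # -- activations -------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y ** 2))
        out._backward = backward
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))
        out._backward = backward
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))
        out._backward = backward
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * y)
        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = backward
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))
        # basic indexing (ints/slices) selects disjoint elements, so the
        # scatter in the backward pass can use plain assignment
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:
                    full[key] = g
                else:
                    np.add.at(full, key, g)
                self._accumulate(full)
        out._backward = backward
        return out

    def softmax(self, axis=-1):
        """Numerically stable softmax along ``axis``."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))
        out._backward = backward
        return out

    # -- graph traversal -----------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Tensor] = []
        discovered = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in discovered:
                continue
            discovered.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in discovered and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(np.squeeze(part, axis=axis))
    out._backward = backward
    return out
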