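"""Gradient-descent optimizers (RMSprop and Adam) for autodiff tensors."""

from __future__ import annotations

from typing import List

import numpy as np

from .autodiff import Tensor

__all__ = ["RMSprop", "Adam", "make_optimizer"]


class Optimizer:
    def __init__(self, params: List[Tensor], lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class RMSprop(Optimizer):
    """RMSprop with Keras-style defaults (rho 0.9, eps 1e-7)."""

    def __init__(self, params, lr: float, rho: float = 0.9,
                 eps: float = 1e-7):
        super().__init__(params, lr)
        self.rho = rho
        self.eps = eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    """Adam with the usual defaults (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, params, lr: float) -> Optimizer:
    name = name.lower()
    if name == "rmsprop":
        return RMSprop(params, lr)
    if name == "adam":
        return Adam(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")
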