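"""First-order optimizers operating in place on (param, grad) pairs."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "RMSprop", "make_optimizer"]


class Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self._state: dict[str, dict] = {}

    def step(self, param_items) -> None:
        """``param_items``: iterable of (key, param_array, grad_array)."""
        for key, p, g in param_items:
            self._update(self._state.setdefault(key, {}), p, g)

    def _update(self, state, p, g):  # pragma: no cover - interface
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float = 1e-2, momentum: float = 0.0):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, state, p, g):
        if self.momentum:
            v = state.setdefault("v", np.zeros_like(p))
            v *= self.momentum
            v -= self.lr * g
            p += v
        else:
            p -= self.lr * g


class RMSprop(Optimizer):
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, state, p, g):
        cache = state.setdefault("cache", np.zeros_like(p))
        cache *= self.rho
        cache += (1.0 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(cache) + self.eps)


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, state, p, g):
        m = state.setdefault("m", np.zeros_like(p))
        v = state.setdefault("v", np.zeros_like(p))
        t = state["t"] = state.get("t", 0) + 1
        m *= self.beta1
        m += (1.0 - self.beta1) * g
        v *= self.beta2
        v += (1.0 - self.beta2) * g * g
        mhat = m / (1.0 - self.beta1**t)
        vhat = v / (1.0 - self.beta2**t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, lr: float) -> Optimizer:
    name = name.lower()
    if name == "sgd":
        return SGD(lr=lr)
    if name == "adam":
        return Adam(lr=lr)
    if name == "rmsprop":
        return RMSprop(lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
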