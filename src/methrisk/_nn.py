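"""Minimal NumPy neural-network primitives shared by the clock and the
stage classifier: activations with derivatives, Glorot initialization and an
Adam optimizer.  Everything is deterministic given a seeded Generator and a
fixed thread count; parameters live in plain ``{name: ndarray}`` dicts so
models serialize trivially."""

from __future__ import annotations

import numpy as np

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


def selu(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))


def selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


ACTIVATIONS = {
    "relu": (relu, relu_grad),
    "selu": (selu, selu_grad),
}


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Adam:
    """Adam optimizer over a named parameter dict (in-place updates)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if name not in self._m:
                self._m[name] = np.zeros_like(g)
                self._v[name] = np.zeros_like(g)
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PlateauScheduler:
    """Decay the learning rate by ``factor`` whenever the best loss has not
    improved by more than ``rel_tol`` (relative) for ``patience`` consecutive
    epochs; the stagnation counter resets after each decay."""

    def __init__(self, optimizer: Adam, patience: int = 30,
                 factor: float = 0.2, rel_tol: float = 1e-4) -> None:
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.rel_tol = rel_tol
        self.best = np.inf
        self.stagnant = 0

    def update(self, loss: float) -> None:
        if loss < self.best * (1.0 - self.rel_tol) or not np.isfinite(self.best):
            self.best = loss
            self.stagnant = 0
            return
        self.stagnant += 1
        if self.stagnant >= self.patience:
            self.opt.lr *= self.factor
            self.stagnant = 0
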