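"""Adam optimizer and the binary cross-entropy objective."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam", "bce_with_logits", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    pos_weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean per-sample binary cross-entropy, computed from logits.

    Numerically stable form ``max(z,0) - z*y + log1p(exp(-|z|))``. With
    ``pos_weight`` > 1 the positive-class terms are up-weighted (useful when
    the event class occupies a minority of samples). Returns the scalar
    loss and its gradient w.r.t. the logits.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    w = 1.0 + (pos_weight - 1.0) * y
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.mean(w * per))
    grad = ((w * (sigmoid(z) - y)) / z.size).astype(logits.dtype)
    return loss, grad


class Adam:
    """Adaptive-moment estimation with bias correction.

    L2 regularization is applied through each parameter's ``weight_decay``
    (added to the raw gradient, i.e. a penalty-term gradient, not decoupled
    decay).
    """

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7,
                 clipnorm: float | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.clipnorm = clipnorm
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        if self.clipnorm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params))
            if total > self.clipnorm:
                scale = self.clipnorm / total
                for p in self.params:
                    p.grad *= scale
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if p.weight_decay:
                g = g + p.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
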