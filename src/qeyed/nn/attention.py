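"""Multi-head self-attention for temporal sequences."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param, glorot

__all__ = ["MultiHeadSelfAttention"]


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention with ``heads`` parallel heads.

    Input and output are (B, T, C) with C divisible by the head count; each
    head attends over the full sequence, so memory grows as O(T^2) — pool
    long sequences before applying this layer.
    """

    def __init__(self, ch: int, heads: int, rng: np.random.Generator,
                 weight_decay: float = 0.0, dtype=np.float32):
        if ch % heads:
            raise ValueError(f"channels {ch} not divisible by heads {heads}")
        self.h = heads
        self.d = ch // heads
        self.Wq = Param(glorot(rng, (ch, ch), ch, ch, dtype), weight_decay, "mhsa.Wq")
        self.Wk = Param(glorot(rng, (ch, ch), ch, ch, dtype), weight_decay, "mhsa.Wk")
        self.Wv = Param(glorot(rng, (ch, ch), ch, ch, dtype), weight_decay, "mhsa.Wv")
        self.Wo = Param(glorot(rng, (ch, ch), ch, ch, dtype), weight_decay, "mhsa.Wo")
        self.bo = Param(np.zeros(ch, dtype=dtype), 0.0, "mhsa.bo")

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        return x.reshape(B, T, self.h, self.d).transpose(0, 2, 1, 3)  # (B,h,T,d)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * d)

    def forward(self, x, train=False):
        self._x = x
        q = self._split(x @ self.Wq.value)
        k = self._split(x @ self.Wk.value)
        v = self._split(x @ self.Wv.value)
        scale = 1.0 / np.sqrt(self.d)
        A = _softmax(q @ k.transpose(0, 1, 3, 2) * scale)  # (B,h,T,T)
        ctx = self._merge(A @ v)  # (B,T,C)
        self._cache = (q, k, v, A, ctx)
        return ctx @ self.Wo.value + self.bo.value

    def backward(self, grad):
        q, k, v, A, ctx = self._cache
        x = self._x
        B, T, C = x.shape
        g2 = grad.reshape(B * T, C)
        self.Wo.grad += ctx.reshape(B * T, C).T @ g2
        self.bo.grad += g2.sum(axis=0)
        dctx = self._split(grad @ self.Wo.value.T)  # (B,h,T,d)
        dA = dctx @ v.transpose(0, 1, 3, 2)  # (B,h,T,T)
        dv = A.transpose(0, 1, 3, 2) @ dctx
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(self.d)
        dq = dS @ k * scale
        dk = dS.transpose(0, 1, 3, 2) @ q * scale
        x2 = x.reshape(B * T, C)
        dx = np.zeros_like(x)
        for dz, W in ((dq, self.Wq), (dk, self.Wk), (dv, self.Wv)):
            dz_m = self._merge(dz)
            W.grad += x2.T @ dz_m.reshape(B * T, C)
            dx += dz_m @ W.value.T
        return dx

    def params(self):
        return [self.Wq, self.Wk, self.Wv, self.Wo, self.bo]
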