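"""Core layers of the sequence-labeling engine.

All layers operate on arrays of shape ``(batch, time, channels)`` and
implement explicit ``forward``/``backward`` passes (reverse-mode gradients
written out by hand). Activations are float32 by default; float64 is
supported for gradient checking.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv1D",
    "Dense",
    "MaxPool1D",
    "Upsample1D",
    "PadTo",
    "PositionalEncoding",
    "CropLike",
    "BatchNorm1D",
    "LayerNorm",
    "Residual",
    "glorot",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "weight_decay", "name")

    def __init__(self, value: np.ndarray, weight_decay: float = 0.0, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.weight_decay = weight_decay
        self.name = name


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int,
           dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad

    def params(self):
        return [p for lay in self.layers for p in lay.params()]


def _relu_backward(grad: np.ndarray, pre: np.ndarray) -> np.ndarray:
    return grad * (pre > 0)


class Conv1D(Layer):
    """Same-padded 1-D convolution with optional fused ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 activation: str | None = None, weight_decay: float = 0.0, dtype=np.float32):
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.k = kernel
        self.in_ch = in_ch
        self.act = activation
        self.pl, self.pr = (kernel - 1) // 2, kernel // 2
        self.W = Param(glorot(rng, (in_ch * kernel, out_ch), in_ch * kernel, out_ch, dtype),
                       weight_decay, "conv.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), 0.0, "conv.b")

    def forward(self, x, train=False):
        B, T, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pl, self.pr), (0, 0)))
        cols = sliding_window_view(xp, self.k, axis=1)  # (B, T, C, k)
        # sliding_window_view yields taps ordered (channel, tap); W is stored
        # (channel*tap, out) in the same order, so no permutation is needed
        self._cols = np.ascontiguousarray(cols).reshape(B, T, C * self.k)
        pre = self._cols @ self.W.value + self.b.value
        if self.act == "relu":
            self._pre = pre
            return np.maximum(pre, 0)
        return pre

    def backward(self, grad):
        if self.act == "relu":
            grad = _relu_backward(grad, self._pre)
        B, T, _ = grad.shape
        C, k = self.in_ch, self.k
        cols2 = self._cols.reshape(B * T, C * k)
        g2 = grad.reshape(B * T, -1)
        self.W.grad += cols2.T @ g2
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.T).reshape(B, T, C, k)
        dxp = np.zeros((B, T + self.pl + self.pr, C), dtype=grad.dtype)
        for j in range(k):
            dxp[:, j : j + T, :] += dcols[:, :, :, j]
        return dxp[:, self.pl : self.pl + T, :]

    def params(self):
        return [self.W, self.b]


class Dense(Layer):
    """Position-wise affine map, optionally fused ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 activation: str | None = None, weight_decay: float = 0.0, dtype=np.float32):
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.act = activation
        self.W = Param(glorot(rng, (in_ch, out_ch), in_ch, out_ch, dtype), weight_decay, "dense.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), 0.0, "dense.b")

    def forward(self, x, train=False):
        self._x = x
        pre = x @ self.W.value + self.b.value
        if self.act == "relu":
            self._pre = pre
            return np.maximum(pre, 0)
        return pre

    def backward(self, grad):
        if self.act == "relu":
            grad = _relu_backward(grad, self._pre)
        B, T, _ = grad.shape
        x2 = self._x.reshape(B * T, -1)
        g2 = grad.reshape(B * T, -1)
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return (g2 @ self.W.value.T).reshape(self._x.shape)

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._pre = x
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * (self._pre > 0)


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.p = pool

    def forward(self, x, train=False):
        B, T, C = x.shape
        if T % self.p:
            raise ValueError(f"sequence length {T} not divisible by pool {self.p}; pad first")
        xr = x.reshape(B, T // self.p, self.p, C)
        self._idx = xr.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        B, T, C = self._shape
        dxr = np.zeros((B, T // self.p, self.p, C), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :], grad[:, :, None, :], axis=2)
        return dxr.reshape(B, T, C)


class Upsample1D(Layer):
    """Nearest-neighbour temporal upsampling by an integer factor."""

    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, x, train=False):
        self._T = x.shape[1]
        return np.repeat(x, self.f, axis=1)

    def backward(self, grad):
        B, Tf, C = grad.shape
        return grad.reshape(B, self._T, self.f, C).sum(axis=2)


class PadTo(Layer):
    """Zero-pad the time axis at the end to a multiple of ``multiple``."""

    def __init__(self, multiple: int):
        self.m = multiple
        self.orig_T: int | None = None

    def forward(self, x, train=False):
        T = x.shape[1]
        self.orig_T = T
        extra = (-T) % self.m
        self._extra = extra
        if extra == 0:
            return x
        return np.pad(x, ((0, 0), (0, extra), (0, 0)))

    def backward(self, grad):
        if self._extra == 0:
            return grad
        return grad[:, : -self._extra, :]


class CropLike(Layer):
    """Crop the time axis back to the length recorded by a paired PadTo."""

    def __init__(self, pad: PadTo):
        self.pad = pad

    def forward(self, x, train=False):
        T = self.pad.orig_T
        self._extra = x.shape[1] - T
        if self._extra < 0:
            raise ValueError("cannot crop to a longer sequence")
        return x[:, :T, :] if self._extra else x

    def backward(self, grad):
        if self._extra == 0:
            return grad
        return np.pad(grad, ((0, 0), (0, self._extra), (0, 0)))


class BatchNorm1D(Layer):
    """Channel-wise batch normalization over (batch, time)."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype), 0.0, "bn.gamma")
        self.beta = Param(np.zeros(ch, dtype=dtype), 0.0, "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma.value
        if not self._train:
            return dxhat / self._std
        n = xhat.shape[0] * xhat.shape[1]
        return (dxhat - dxhat.mean(axis=(0, 1)) - xhat * (dxhat * xhat).mean(axis=(0, 1))) / self._std

    def params(self):
        return [self.gamma, self.beta]


class LayerNorm(Layer):
    """Per-position normalization over the channel axis."""

    def __init__(self, ch: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype), 0.0, "ln.gamma")
        self.beta = Param(np.zeros(ch, dtype=dtype), 0.0, "ln.beta")
        self.eps = eps

    def forward(self, x, train=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma.value
        c = xhat.shape[-1]
        return (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)) / self._std

    def params(self):
        return [self.gamma, self.beta]


class PositionalEncoding(Layer):
    """Adds the fixed sinusoidal position code; needed ahead of attention,
    which is otherwise permutation-equivariant."""

    def __init__(self, ch: int, max_len: int = 8192, scale: float = 1.0, dtype=np.float32):
        pos = np.arange(max_len)[:, None]
        i = np.arange(ch)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / ch)
        pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        self.pe = (scale * pe).astype(dtype)

    def forward(self, x, train=False):
        return x + self.pe[: x.shape[1]]

    def backward(self, grad):
        return grad


class Residual(Layer):
    """y = x + inner(x); requires inner to preserve shape."""

    def __init__(self, inner: Layer):
        self.inner = inner

    def forward(self, x, train=False):
        return x + self.inner.forward(x, train)

    def backward(self, grad):
        return grad + self.inner.backward(grad)

    def params(self):
        return self.inner.params()
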