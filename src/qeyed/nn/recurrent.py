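"""Gated recurrent layers (LSTM, GRU) with hand-written backpropagation
through time.

The gating follows the standard formulation: an LSTM cell keeps a memory
vector updated by forget/input gates and exposes it through an output gate,

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
    g_t = tanh   (W_c [h_{t-1}, x_t] + b_c)
    C_t = f_t * C_{t-1} + i_t * g_t
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
    h_t = o_t * tanh(C_t)

while the GRU merges the memory into the hidden state with update/reset
gates. Input-side projections are computed for the whole sequence in one
matrix product; only the hidden-to-hidden recursion loops over time, with
the sigmoid gates stacked contiguously so each step needs a single
sigmoid/tanh evaluation.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param, glorot

__all__ = ["LSTM", "GRU", "Bidirectional"]


def _orthogonal_gates(rng: np.random.Generator, hidden: int, n_gates: int,
                      dtype=np.float32) -> np.ndarray:
    """Stacked (H, n_gates*H) recurrent matrix with an orthogonal block per
    gate — the standard initialization for gated recurrent layers, which
    keeps hidden-state norms stable through long sequences."""
    blocks = []
    for _ in range(n_gates):
        a = rng.standard_normal((hidden, hidden))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1).astype(dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Unidirectional LSTM returning the full hidden sequence (B, T, H).

    Sigmoid gates are stacked (i, f, o) ahead of the tanh candidate g; the
    forget-gate bias is initialized to 1 (standard remedy for premature
    forgetting). L2 weight decay applies to the input kernel only,
    mirroring how kernel regularizers are conventionally scoped in
    recurrent layers.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False, weight_decay: float = 0.0, dtype=np.float32):
        H = hidden
        self.H = H
        self.reverse = reverse
        self.Wx = Param(glorot(rng, (in_dim, 4 * H), in_dim, H, dtype), weight_decay, "lstm.Wx")
        self.Wh = Param(_orthogonal_gates(rng, H, 4, dtype), 0.0, "lstm.Wh")
        b = np.zeros(4 * H, dtype=dtype)
        b[H : 2 * H] = 1.0  # forget gate block
        self.b = Param(b, 0.0, "lstm.b")

    def forward(self, x, train=False):
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        H = self.H
        self._x = x
        Zx = x @ self.Wx.value + self.b.value  # (B,T,4H)
        S = np.empty((B, T, 3 * H), dtype=x.dtype)  # i, f, o after sigmoid
        G = np.empty((B, T, H), dtype=x.dtype)
        Cs = np.empty_like(G); TC = np.empty_like(G); Hs = np.empty_like(G)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        Wh = self.Wh.value
        for t in range(T):
            z = Zx[:, t] + h @ Wh
            s = _sigmoid(z[:, : 3 * H])
            g = np.tanh(z[:, 3 * H :])
            c = s[:, H : 2 * H] * c + s[:, :H] * g
            tc = np.tanh(c)
            h = s[:, 2 * H :] * tc
            S[:, t] = s; G[:, t] = g; Cs[:, t] = c; TC[:, t] = tc; Hs[:, t] = h
        self._cache = (S, G, Cs, TC, Hs)
        return Hs[:, ::-1, :] if self.reverse else Hs

    def backward(self, grad):
        if self.reverse:
            grad = grad[:, ::-1, :]
        S, G, Cs, TC, Hs = self._cache
        x = self._x
        B, T, H = G.shape
        Wh = self.Wh.value
        dZ = np.empty((B, T, 4 * H), dtype=grad.dtype)
        dWh = np.zeros_like(self.Wh.value)
        dh_next = np.zeros((B, H), dtype=grad.dtype)
        dc_next = np.zeros((B, H), dtype=grad.dtype)
        zero = np.zeros((B, H), dtype=grad.dtype)
        for t in range(T - 1, -1, -1):
            s, g, tc = S[:, t], G[:, t], TC[:, t]
            i, f, o = s[:, :H], s[:, H : 2 * H], s[:, 2 * H :]
            c_prev = Cs[:, t - 1] if t > 0 else zero
            h_prev = Hs[:, t - 1] if t > 0 else zero
            dh = grad[:, t] + dh_next
            dc = dc_next + dh * o * (1 - tc * tc)
            dz = dZ[:, t]
            dz[:, :H] = dc * g
            dz[:, H : 2 * H] = dc * c_prev
            dz[:, 2 * H : 3 * H] = dh * tc
            dz[:, : 3 * H] *= s * (1 - s)
            dz[:, 3 * H :] = dc * i * (1 - g * g)
            dc_next = dc * f
            dWh += h_prev.T @ dz
            dh_next = dz @ Wh.T
        dZ2 = dZ.reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, -1).T @ dZ2
        self.Wh.grad += dWh
        self.b.grad += dZ2.sum(axis=0)
        dx = (dZ2 @ self.Wx.value.T).reshape(x.shape)
        return dx[:, ::-1, :] if self.reverse else dx

    def params(self):
        return [self.Wx, self.Wh, self.b]


class GRU(Layer):
    """Unidirectional GRU returning the full hidden sequence.

    h_t = (1 - z_t) * n_t + z_t * h_{t-1}, with the reset gate r_t applied
    to the hidden-side contribution of the candidate n_t. Sigmoid gates are
    stacked (r, z) ahead of the tanh candidate.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False, weight_decay: float = 0.0, dtype=np.float32):
        H = hidden
        self.H = H
        self.reverse = reverse
        self.Wx = Param(glorot(rng, (in_dim, 3 * H), in_dim, H, dtype), weight_decay, "gru.Wx")
        self.Wh = Param(_orthogonal_gates(rng, H, 3, dtype), 0.0, "gru.Wh")
        self.bx = Param(np.zeros(3 * H, dtype=dtype), 0.0, "gru.bx")
        self.bh = Param(np.zeros(3 * H, dtype=dtype), 0.0, "gru.bh")

    def forward(self, x, train=False):
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        H = self.H
        self._x = x
        Zx = x @ self.Wx.value + self.bx.value
        S = np.empty((B, T, 2 * H), dtype=x.dtype)  # r, z after sigmoid
        N = np.empty((B, T, H), dtype=x.dtype)
        HN = np.empty_like(N); Hs = np.empty_like(N)
        h = np.zeros((B, H), dtype=x.dtype)
        Wh, bh = self.Wh.value, self.bh.value
        for t in range(T):
            zh = h @ Wh + bh
            s = _sigmoid(Zx[:, t, : 2 * H] + zh[:, : 2 * H])
            hn = zh[:, 2 * H :]
            n = np.tanh(Zx[:, t, 2 * H :] + s[:, :H] * hn)
            h = (1 - s[:, H:]) * n + s[:, H:] * h
            S[:, t] = s; N[:, t] = n; HN[:, t] = hn; Hs[:, t] = h
        self._cache = (S, N, HN, Hs)
        return Hs[:, ::-1, :] if self.reverse else Hs

    def backward(self, grad):
        if self.reverse:
            grad = grad[:, ::-1, :]
        S, N, HN, Hs = self._cache
        x = self._x
        B, T, H = N.shape
        Wh = self.Wh.value
        dZx = np.empty((B, T, 3 * H), dtype=grad.dtype)
        dWh = np.zeros_like(self.Wh.value)
        dbh = np.zeros_like(self.bh.value)
        dh_next = np.zeros((B, H), dtype=grad.dtype)
        dzh = np.empty((B, 3 * H), dtype=grad.dtype)
        zero = np.zeros((B, H), dtype=grad.dtype)
        for t in range(T - 1, -1, -1):
            s, n, hn = S[:, t], N[:, t], HN[:, t]
            r, z = s[:, :H], s[:, H:]
            h_prev = Hs[:, t - 1] if t > 0 else zero
            dh = grad[:, t] + dh_next
            dn_pre = dh * (1 - z) * (1 - n * n)
            dzh[:, :H] = dn_pre * hn            # -> reset gate pre-activation
            dzh[:, H : 2 * H] = dh * (h_prev - n)  # -> update gate pre-activation
            dzh[:, : 2 * H] *= s * (1 - s)
            dzh[:, 2 * H :] = dn_pre * r
            dZx[:, t, : 2 * H] = dzh[:, : 2 * H]
            dZx[:, t, 2 * H :] = dn_pre
            dWh += h_prev.T @ dzh
            dbh += dzh.sum(axis=0)
            dh_next = dh * z + dzh @ Wh.T
        dZx2 = dZx.reshape(B * T, 3 * H)
        self.Wx.grad += x.reshape(B * T, -1).T @ dZx2
        self.bx.grad += dZx2.sum(axis=0)
        self.Wh.grad += dWh
        self.bh.grad += dbh
        dx = (dZx2 @ self.Wx.value.T).reshape(x.shape)
        return dx[:, ::-1, :] if self.reverse else dx

    def params(self):
        return [self.Wx, self.Wh, self.bx, self.bh]


class Bidirectional(Layer):
    """Runs a forward and a time-reversed cell, concatenating hidden states.

    Output has ``2 * hidden`` channels.
    """

    def __init__(self, kind: str, in_dim: int, hidden: int, rng: np.random.Generator,
                 weight_decay: float = 0.0, dtype=np.float32):
        cell = {"lstm": LSTM, "gru": GRU}[kind]
        self.fwd = cell(in_dim, hidden, rng, reverse=False, weight_decay=weight_decay, dtype=dtype)
        self.bwd = cell(in_dim, hidden, rng, reverse=True, weight_decay=weight_decay, dtype=dtype)
        self.H = hidden

    def forward(self, x, train=False):
        return np.concatenate([self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=-1)

    def backward(self, grad):
        return self.fwd.backward(grad[:, :, : self.H]) + self.bwd.backward(grad[:, :, self.H:])

    def params(self):
        return self.fwd.params() + self.bwd.params()
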