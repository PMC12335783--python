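"""Numerical gradient checks and contracts of the sequence-labeling engine."""

import numpy as np
import pytest

from qeyed import nn


def _num_grad_input(layer, x, g_out, idx, train, eps=1e-6):
    xp = x.copy(); xp[idx] += eps
    xm = x.copy(); xm[idx] -= eps
    return ((layer.forward(xp, train) * g_out).sum()
            - (layer.forward(xm, train) * g_out).sum()) / (2 * eps)


def _num_grad_param(layer, x, g_out, p, idx, train, eps=1e-6):
    old = p.value[idx]
    p.value[idx] = old + eps
    lp = (layer.forward(x, train) * g_out).sum()
    p.value[idx] = old - eps
    lm = (layer.forward(x, train) * g_out).sum()
    p.value[idx] = old
    return (lp - lm) / (2 * eps)


def _check_layer(layer, x, train=True, tol=1e-5):
    y = layer.forward(x, train)
    g_out = np.random.default_rng(1).standard_normal(y.shape)
    for p in layer.params():
        p.grad[...] = 0
    layer.forward(x, train)
    dx = layer.backward(g_out)
    rng = np.random.default_rng(2)
    for _ in range(5):
        idx = tuple(rng.integers(0, s) for s in x.shape)
        num = _num_grad_input(layer, x, g_out, idx, train)
        assert abs(num - dx[idx]) < tol * max(1.0, abs(num)), f"dx at {idx}"
    for p in layer.params():
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            for q in layer.params():
                q.grad[...] = 0
            layer.forward(x, train)
            layer.backward(g_out)
            num = _num_grad_param(layer, x, g_out, p, idx, train)
            assert abs(num - p.grad[idx]) < tol * max(1.0, abs(num)), f"{p.name} at {idx}"


@pytest.mark.parametrize("make", [
    lambda r: nn.Conv1D(4, 5, 3, r, dtype=np.float64),
    lambda r: nn.Conv1D(4, 5, 4, r, activation="relu", dtype=np.float64),
    lambda r: nn.Dense(4, 6, r, activation="relu", dtype=np.float64),
    lambda r: nn.MaxPool1D(2),
    lambda r: nn.Upsample1D(3),
    lambda r: nn.BatchNorm1D(4, dtype=np.float64),
    lambda r: nn.LayerNorm(4, dtype=np.float64),
    lambda r: nn.MultiHeadSelfAttention(4, 2, r, dtype=np.float64),
    lambda r: nn.LSTM(4, 5, r, dtype=np.float64),
    lambda r: nn.GRU(4, 5, r, dtype=np.float64),
    lambda r: nn.Bidirectional("lstm", 4, 3, r, dtype=np.float64),
    lambda r: nn.Bidirectional("gru", 4, 3, r, dtype=np.float64),
    lambda r: nn.Residual(nn.Sequential([nn.LayerNorm(4, dtype=np.float64),
                                         nn.MultiHeadSelfAttention(4, 2, r, dtype=np.float64)])),
], ids=["conv", "conv_relu", "dense_relu", "maxpool", "upsample", "batchnorm",
        "layernorm", "attention", "lstm", "gru", "bilstm", "bigru", "residual_attn"])
def test_layer_gradients_match_finite_differences(make):
    rng = np.random.default_rng(0)
    layer = make(rng)
    x = rng.standard_normal((3, 12, 4))
    _check_layer(layer, x)


def test_pad_crop_roundtrip_gradients():
    rng = np.random.default_rng(0)
    pad = nn.PadTo(8)
    seq = nn.Sequential([pad, nn.Conv1D(4, 4, 3, rng, dtype=np.float64), nn.CropLike(pad)])
    x = rng.standard_normal((2, 13, 4))
    y = seq.forward(x, train=True)
    assert y.shape == (2, 13, 4)
    _check_layer(seq, x)


def test_batchnorm_eval_uses_running_stats():
    rng = np.random.default_rng(0)
    bn = nn.BatchNorm1D(2)
    x = rng.standard_normal((4, 10, 2)).astype(np.float32) * 3 + 1
    for _ in range(200):
        bn.forward(x, train=True)
    y = bn.forward(x, train=False)
    # after many updates the running stats approach the batch stats
    assert abs(float(y.mean())) < 0.05
    assert abs(float(y.std()) - 1.0) < 0.05


def test_bce_with_logits_matches_reference():
    rng = np.random.default_rng(3)
    z = rng.standard_normal((5, 7, 1))
    y = (rng.uniform(size=z.shape) < 0.3).astype(float)
    loss, grad = nn.bce_with_logits(z, y)
    p = nn.sigmoid(z)
    ref = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert abs(loss - ref) < 1e-9
    np.testing.assert_allclose(grad, (p - y) / z.size, rtol=1e-6)


def test_bce_pos_weight_scales_positive_terms():
    z = np.zeros((1, 4, 1))
    y = np.array([1.0, 1.0, 0.0, 0.0]).reshape(1, 4, 1)
    base, _ = nn.bce_with_logits(z, y, pos_weight=1.0)
    up, _ = nn.bce_with_logits(z, y, pos_weight=3.0)
    assert np.isclose(up, base * 2.0)  # half the terms tripled -> x2 mean


def test_adam_decreases_quadratic():
    p = nn.Param(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.05)
    for _ in range(500):
        opt.zero_grad()
        p.grad[...] = 2 * p.value
        opt.step()
    assert np.all(np.abs(p.value) < 1e-2)


def test_weight_decay_shrinks_parameters():
    p = nn.Param(np.array([1.0]), weight_decay=0.5)
    opt = nn.Adam([p], lr=0.01)
    for _ in range(200):
        opt.zero_grad()  # no data gradient; only the L2 pull
        opt.step()
    assert abs(p.value[0]) < 1.0


def test_positional_encoding_is_additive_and_gradient_transparent():
    pe = nn.PositionalEncoding(4, scale=0.5)
    x = np.zeros((2, 9, 4), dtype=np.float32)
    y = pe.forward(x)
    assert not np.allclose(y, 0)
    g = np.ones_like(y)
    np.testing.assert_array_equal(pe.backward(g), g)
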