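"""Per-sample Quiet-Eye classifiers: an RBF-SVM baseline and five
sequence-labeling networks.

Every detector maps a length-L segment of (standardized) EOG amplitudes to
a length-L trace of QE probabilities, thresholded at 0.5 into a binary
mask. The six families:

``svm``
    Each timepoint is treated as a separate sample of one standardized
    amplitude value, classified by a support-vector machine with RBF
    kernel — the conventional, temporally blind baseline.
``cnn1d``
    Two convolutions (64, 128 filters), max-pooling, upsampling and a
    pointwise head: fast local pattern matching.
``transformer``
    A 64-filter convolution front-end with layer normalization and
    residual multi-head self-attention; the sequence is pooled 4x before
    attention (memory is quadratic in length) and upsampled after.
``unet``
    A three-level 1-D encoder/decoder (64, 128, 256 filters) with skip
    connections — segmentation-style region labeling.
``cnn_gru`` / ``cnn_lstm``
    A convolutional front-end feeding bidirectional gated recurrent
    layers, then a time-distributed dense layer. The LSTM variant uses
    two bidirectional layers of 200 and 100 units plus a 50-unit dense
    layer (L2 regularization 0.001, conv kernels 5 and 3, batch
    normalization).

Networks are trained with per-sample binary cross-entropy from sigmoid
heads (computed internally from logits for numerical stability) using Adam
at learning rate 0.001. Normalization statistics are learned from the
training split only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from . import nn
from .segmenter import Segment

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "TrainConfig",
    "PredictionTrace",
    "TrainedModel",
    "build",
    "fit",
    "predict",
]

logger = logging.getLogger(__name__)

FAMILIES = ("svm", "cnn1d", "transformer", "unet", "cnn_gru", "cnn_lstm")

#: architecture constants per family; overridable through ModelSpec.params
_DEFAULTS: dict[str, dict] = {
    "svm": dict(C=1.0, gamma="scale", context=0, max_train_points=4000),
    "cnn1d": dict(filters=(64, 128), kernels=(7, 3), pool=2, time_channel=True),
    "transformer": dict(filters=64, kernel=3, heads=4, pool=4, time_channel=True),
    "unet": dict(filters=(64, 128, 256), kernel=3, time_channel=True),
    "cnn_gru": dict(filters=(64, 128), kernels=(5, 3), pool=2, units=(100, 50), dense=50, l2=0.0,
                    time_channel=True),
    "cnn_lstm": dict(filters=(64, 128), kernels=(5, 3), pool=2, units=(200, 100), dense=50, l2=1e-3,
                     time_channel=True),
}


@dataclass(frozen=True)
class ModelSpec:
    """A detector family plus its layer parameters and decision threshold."""

    family: str
    params: dict = field(default_factory=dict)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        unknown = set(self.params) - set(_DEFAULTS[self.family])
        if unknown:
            raise ValueError(f"unknown parameters for {self.family}: {sorted(unknown)}")

    def resolved(self) -> dict:
        return {**_DEFAULTS[self.family], **self.params}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, lr 0.001, binary cross-entropy, 50 epochs)."""

    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 8
    loss: str = "binary_cross_entropy"
    optimizer: str = "adam"
    seed: int = 0
    validation_fraction: float = 0.2
    pos_weight: float = 1.0  # >1 up-weights QE samples in the loss
    clipnorm: float | None = None  # global gradient-norm clip (None = off)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.pos_weight <= 0:
            raise ValueError("pos_weight must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss != "binary_cross_entropy":
            raise ValueError("only binary_cross_entropy loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class PredictionTrace:
    """Per-sample QE probabilities and the thresholded binary mask."""

    probs: np.ndarray
    mask: np.ndarray


class _UNet(nn.Layer):
    """Three-level 1-D U-Net with channel-concatenating skip connections."""

    def __init__(self, filters: tuple[int, int, int], kernel: int, rng, in_ch: int = 1,
                 dtype=np.float32):
        f1, f2, f3 = filters
        k = kernel
        conv = lambda i, o, kk=k: nn.Conv1D(i, o, kk, rng, activation="relu", dtype=dtype)
        self.pad = nn.PadTo(8)
        self.enc = [conv(in_ch, f1), conv(f1, f2), conv(f2, f3)]
        self.pools = [nn.MaxPool1D(2) for _ in range(3)]
        self.bottleneck = conv(f3, f3)
        self.ups = [nn.Upsample1D(2) for _ in range(3)]
        self.dec = [conv(f3 + f3, f2), conv(f2 + f2, f1), conv(f1 + f1, f1)]
        self.crop = nn.CropLike(self.pad)
        self.head = nn.Conv1D(f1, 1, 1, rng, dtype=dtype)

    def forward(self, x, train=False):
        x = self.pad.forward(x, train)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_ch = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_ch.append(skip.shape[-1])
            x = dec.forward(np.concatenate([x, skip], axis=-1), train)
        x = self.crop.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, grad):
        grad = self.head.backward(grad)
        grad = self.crop.backward(grad)
        dskips = []
        for up, dec, ch in zip(reversed(self.ups), reversed(self.dec), reversed(self._skip_ch)):
            g = dec.backward(grad)
            dskips.append(g[:, :, -ch:])
            grad = up.backward(g[:, :, :-ch])
        grad = self.bottleneck.backward(grad)
        # dskips were collected shallowest-first; align with deep->shallow encoder walk
        dskips = dskips[::-1]
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pools), dskips):
            grad = pool.backward(grad) + dskip
            grad = enc.backward(grad)
        return self.pad.backward(grad)

    def params(self):
        layers = self.enc + [self.bottleneck] + self.dec + [self.head]
        return [p for lay in layers for p in lay.params()]


def _build_net(spec: ModelSpec, input_length: int, rng: np.random.Generator) -> nn.Layer:
    p = spec.resolved()
    fam = spec.family
    in_ch = 2 if p.get("time_channel") else 1
    if fam == "cnn1d":
        f1, f2 = p["filters"]
        k1, k2 = p["kernels"]
        pad = nn.PadTo(p["pool"])
        return nn.Sequential([
            pad,
            nn.Conv1D(in_ch, f1, k1, rng, activation="relu"),
            nn.Conv1D(f1, f2, k2, rng, activation="relu"),
            nn.MaxPool1D(p["pool"]),
            nn.Upsample1D(p["pool"]),
            nn.CropLike(pad),
            nn.Conv1D(f2, 1, 1, rng),
        ])
    if fam == "transformer":
        f = p["filters"]
        pad = nn.PadTo(p["pool"])
        return nn.Sequential([
            pad,
            nn.Conv1D(in_ch, f, p["kernel"], rng, activation="relu"),
            nn.MaxPool1D(p["pool"]),
            nn.PositionalEncoding(f, scale=0.1),
            nn.LayerNorm(f),
            nn.Residual(nn.MultiHeadSelfAttention(f, p["heads"], rng)),
            nn.LayerNorm(f),
            nn.Residual(nn.Sequential([
                nn.Dense(f, f, rng, activation="relu"),
                nn.Dense(f, f, rng),
            ])),
            nn.Upsample1D(p["pool"]),
            nn.CropLike(pad),
            nn.Conv1D(f, 1, 1, rng),
        ])
    if fam == "unet":
        return _UNet(tuple(p["filters"]), p["kernel"], rng, in_ch=in_ch)
    if fam in ("cnn_gru", "cnn_lstm"):
        f1, f2 = p["filters"]
        k1, k2 = p["kernels"]
        kind = "gru" if fam == "cnn_gru" else "lstm"
        wd = p["l2"]
        pad = nn.PadTo(p["pool"])
        layers: list[nn.Layer] = [
            pad,
            nn.Conv1D(in_ch, f1, k1, rng),
            nn.BatchNorm1D(f1),
            nn.ReLU(),
            nn.Conv1D(f1, f2, k2, rng),
            nn.BatchNorm1D(f2),
            nn.ReLU(),
            nn.MaxPool1D(p["pool"]),
        ]
        ch = f2
        for units in p["units"]:
            layers.append(nn.Bidirectional(kind, ch, units, rng, weight_decay=wd))
            ch = 2 * units
        layers.append(nn.Dense(ch, p["dense"], rng, activation="relu", weight_decay=wd))
        layers += [
            nn.Upsample1D(p["pool"]),
            nn.CropLike(pad),
            nn.Dense(p["dense"], 1, rng),
        ]
        return nn.Sequential(layers)
    raise ValueError(f"family {fam} has no network builder")  # pragma: no cover


@dataclass
class UntrainedModel:
    """Output of :func:`build`: architecture bound to an input length."""

    spec: ModelSpec
    input_length: int
    net: nn.Layer | None  # None for the SVM family


@dataclass
class TrainedModel:
    """A fitted detector with its normalization statistics and training log.

    ``history`` holds one dict per epoch with training (and, when a
    validation fraction is configured, validation) loss and per-sample
    accuracy — the learning curves.
    """

    spec: ModelSpec
    input_length: int
    net: nn.Layer | None
    svm: SVC | None
    norm_mean: float
    norm_sd: float
    history: list[dict]

    def predict(self, segments: Sequence[Segment]) -> list[PredictionTrace]:
        return predict(self, segments)


def build(spec: ModelSpec, input_length: int, seed: int = 0) -> UntrainedModel:
    """Instantiate an untrained detector for segments of ``input_length`` samples."""
    if input_length < 8:
        raise ValueError("input_length too short")
    if spec.family == "svm":
        return UntrainedModel(spec, input_length, None)
    rng = np.random.default_rng(seed)
    return UntrainedModel(spec, input_length, _build_net(spec, input_length, rng))


def _stack(segments: Sequence[Segment], L: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.samples for s in segments]).astype(np.float32)[..., None]
    Y = np.stack([s.mask for s in segments]).astype(np.float32)[..., None]
    if X.shape[1] != L:
        raise ValueError(f"segments of length {X.shape[1]} do not match model length {L}")
    return X, Y


def _with_time_channel(X: np.ndarray) -> np.ndarray:
    """Append a normalized elapsed-time channel in [-0.5, 0.5).

    The analysis windows are onset-anchored, so absolute position within a
    window carries label information that shift-invariant convolutions
    cannot access on their own.
    """
    n, L, _ = X.shape
    t = (np.arange(L, dtype=X.dtype) / L - 0.5)[None, :, None]
    return np.concatenate([X, np.broadcast_to(t, (n, L, 1))], axis=-1)


def _forward_batches(net: nn.Layer, X: np.ndarray, batch: int) -> np.ndarray:
    outs = [net.forward(X[i : i + batch], train=False) for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)


def _svm_features(x: np.ndarray, context: int) -> np.ndarray:
    """Per-timepoint feature rows; optional +-context neighbouring samples."""
    n, L = x.shape
    if context == 0:
        return x.reshape(-1, 1)
    pad = np.pad(x, ((0, 0), (context, context)), mode="edge")
    from numpy.lib.stride_tricks import sliding_window_view

    return sliding_window_view(pad, 2 * context + 1, axis=1).reshape(n * L, -1)


def _fit_svm(spec: ModelSpec, segments, cfg: TrainConfig, L: int) -> TrainedModel:
    p = spec.resolved()
    X, Y = _stack(segments, L)
    mean, sd = float(X.mean()), float(X.std() or 1.0)
    feats = _svm_features(((X - mean) / sd)[:, :, 0], p["context"])
    labels = Y.reshape(-1).astype(int)
    rng = np.random.default_rng(cfg.seed)
    cap = int(p["max_train_points"])
    if feats.shape[0] > cap:  # class-stratified subsample keeps training tractable
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        n_pos = min(len(pos), max(cap // 4, int(round(cap * len(pos) / len(labels)))))
        n_neg = cap - n_pos
        sel = np.concatenate([
            rng.choice(pos, size=min(n_pos, len(pos)), replace=False),
            rng.choice(neg, size=min(n_neg, len(neg)), replace=False),
        ])
        feats, labels = feats[sel], labels[sel]
    clf = SVC(C=p["C"], gamma=p["gamma"], kernel="rbf", random_state=cfg.seed)
    clf.fit(feats, labels)
    acc = float(clf.score(feats, labels))
    return TrainedModel(spec, L, None, clf, mean, sd,
                        history=[{"epoch": 1, "loss": math.nan, "acc": acc}])


def fit(model: UntrainedModel, segments: Sequence[Segment], cfg: TrainConfig = TrainConfig()
        ) -> TrainedModel:
    """Train a detector on labelled segments.

    Minimizes mean per-sample binary cross-entropy with Adam; logs loss and
    per-sample accuracy each epoch (plus validation metrics on a held-out
    fraction of the training set). Deterministic given the build seed and
    ``cfg.seed``.
    """
    if not segments:
        raise ValueError("training set must be non-empty")
    L = model.input_length
    if all((s.mask == s.mask[0]).all() for s in segments):
        warnings.warn("all training masks are single-class; training proceeds but the "
                      "detector cannot learn a decision boundary", stacklevel=2)
    if model.spec.family == "svm":
        return _fit_svm(model.spec, segments, cfg, L)

    X, Y = _stack(segments, L)
    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    n_val = int(round(cfg.validation_fraction * n)) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm[:0]
    mean = float(X[tr_idx].mean())
    sd = float(X[tr_idx].std() or 1.0)
    Xn = (X - mean) / sd
    if model.spec.resolved().get("time_channel"):
        Xn = _with_time_channel(Xn)

    net = model.net
    opt = nn.Adam(net.params(), lr=cfg.learning_rate, clipnorm=cfg.clipnorm)
    history: list[dict] = []
    B = cfg.batch_size
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(tr_idx)
        tot_loss = tot_correct = tot_count = 0.0
        for i in range(0, len(order), B):
            idx = order[i : i + B]
            xb, yb = Xn[idx], Y[idx]
            logits = net.forward(xb, train=True)
            loss, dlogits = nn.bce_with_logits(logits, yb, cfg.pos_weight)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            tot_loss += loss * yb.size
            tot_correct += float(((logits >= 0) == (yb >= 0.5)).sum())
            tot_count += yb.size
        entry = {"epoch": epoch, "loss": tot_loss / tot_count, "acc": tot_correct / tot_count}
        if n_val:
            vlogits = _forward_batches(net, Xn[val_idx], B)
            vloss, _ = nn.bce_with_logits(vlogits, Y[val_idx])
            entry["val_loss"] = vloss
            entry["val_acc"] = float(((vlogits >= 0) == (Y[val_idx] >= 0.5)).mean())
        history.append(entry)
        logger.debug("%s epoch %d: %s", model.spec.family, epoch, entry)
    return TrainedModel(model.spec, L, net, None, mean, sd, history)


def predict(model: TrainedModel, segments: Sequence[Segment]) -> list[PredictionTrace]:
    """Per-sample QE probabilities and thresholded masks for each segment."""
    L = model.input_length
    X, _ = _stack(segments, L)
    Xn = (X - model.norm_mean) / model.norm_sd
    thr = model.spec.threshold
    if model.spec.family == "svm":
        p = model.spec.resolved()
        feats = _svm_features(Xn[:, :, 0], p["context"])
        scores = model.svm.decision_function(feats).reshape(len(segments), L)
        probs = nn.sigmoid(scores)
    else:
        if model.spec.resolved().get("time_channel"):
            Xn = _with_time_channel(Xn)
        logits = _forward_batches(model.net, Xn, 8)[:, :, 0]
        probs = nn.sigmoid(logits.astype(np.float64))
    masks = (probs >= thr).astype(np.int8)
    return [PredictionTrace(probs=probs[i], mask=masks[i]) for i in range(len(segments))]
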