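"""Detector contracts: shapes, ranges, determinism, learning on a tiny task."""

import numpy as np
import pytest

from qeyed.detectors import FAMILIES, ModelSpec, TrainConfig, build, fit, predict
from qeyed.segmenter import Segment

FS = 200.0
L = 96  # short segments keep these tests fast

#: scaled-down layer parameters for unit testing
TINY = {
    "svm": {},
    "cnn1d": {"filters": (4, 8), "kernels": (5, 3)},
    "transformer": {"filters": 8, "heads": 2, "pool": 4},
    "unet": {"filters": (4, 6, 8)},
    "cnn_gru": {"filters": (4, 8), "units": (6, 4), "dense": 4},
    "cnn_lstm": {"filters": (4, 8), "units": (8, 6), "dense": 4},
}


def _toy_segments(n=12, seed=0):
    """Separable mini-task: a plateau of distinctive level marks the event."""
    rng = np.random.default_rng(seed)
    segs = []
    for i in range(n):
        x = rng.normal(0, 0.5, L)
        a, b = 30, 30 + int(rng.integers(20, 40))
        x[a:b] += 5.0
        m = np.zeros(L, dtype=int)
        m[a:b] = 1
        segs.append(Segment(x, m, FS, participant_id=f"P{i % 4:02d}", shot_id=i))
    return segs


@pytest.mark.parametrize("family", [f for f in FAMILIES if f != "svm"])
def test_untrained_network_outputs_valid_probabilities(family):
    model = build(ModelSpec(family, params=TINY[family]), L, seed=0)
    x = np.zeros((2, L, 2), dtype=np.float32)  # amplitude + time channel
    out = model.net.forward(x, train=False)
    assert out.shape == (2, L, 1)
    assert np.isfinite(out).all()


def test_unet_pads_non_multiple_lengths():
    model = build(ModelSpec("unet", params=TINY["unet"]), 100, seed=0)
    out = model.net.forward(np.zeros((1, 100, 2), dtype=np.float32), train=False)
    assert out.shape == (1, 100, 1)


@pytest.mark.parametrize("family", list(FAMILIES))
def test_fit_predict_contract(family):
    segs = _toy_segments()
    cfg = TrainConfig(epochs=3, batch_size=4, seed=1, validation_fraction=0.25)
    trained = fit(build(ModelSpec(family, params=TINY[family]), L, seed=1), segs, cfg)
    traces = predict(trained, segs[:3])
    assert len(traces) == 3
    for tr in traces:
        assert tr.probs.shape == (L,)
        assert np.all((tr.probs >= 0) & (tr.probs <= 1))
        np.testing.assert_array_equal(tr.mask, (tr.probs >= 0.5).astype(np.int8))
    again = predict(trained, segs[:3])
    np.testing.assert_array_equal(traces[0].probs, again[0].probs)


def test_training_loss_descends_and_accuracy_high():
    segs = _toy_segments()
    cfg = TrainConfig(epochs=25, batch_size=4, seed=0, validation_fraction=0.0)
    trained = fit(build(ModelSpec("cnn_gru", params=TINY["cnn_gru"]), L, seed=0), segs, cfg)
    losses = [h["loss"] for h in trained.history]
    assert losses[-1] <= losses[0]
    assert trained.history[-1]["acc"] >= 0.95


def test_identical_seeds_reproduce_training_log():
    segs = _toy_segments()
    cfg = TrainConfig(epochs=3, batch_size=4, seed=7, validation_fraction=0.2)
    h1 = fit(build(ModelSpec("cnn1d", params=TINY["cnn1d"]), L, seed=7), segs, cfg).history
    h2 = fit(build(ModelSpec("cnn1d", params=TINY["cnn1d"]), L, seed=7), segs, cfg).history
    assert h1 == h2


def test_validation_metrics_logged():
    segs = _toy_segments()
    cfg = TrainConfig(epochs=2, batch_size=4, seed=0, validation_fraction=0.25)
    trained = fit(build(ModelSpec("cnn1d", params=TINY["cnn1d"]), L, seed=0), segs, cfg)
    assert {"epoch", "loss", "acc", "val_loss", "val_acc"} <= set(trained.history[0])


def test_epochs_zero_rejected():
    with pytest.raises(ValueError, match="epochs"):
        TrainConfig(epochs=0)


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="unknown family"):
        ModelSpec("mlp")


def test_unknown_parameter_rejected():
    with pytest.raises(ValueError, match="unknown parameters"):
        ModelSpec("cnn1d", params={"layers": 3})


def test_single_class_masks_warn_but_train():
    segs = _toy_segments(n=4)
    for s in segs:
        s.mask[:] = 0
    with pytest.warns(UserWarning, match="single-class"):
        fit(build(ModelSpec("cnn1d", params=TINY["cnn1d"]), L, seed=0), segs,
            TrainConfig(epochs=1, batch_size=4, validation_fraction=0.0))


def test_length_mismatch_rejected():
    segs = _toy_segments(n=4)
    trained = fit(build(ModelSpec("svm"), L, seed=0), segs,
                  TrainConfig(epochs=1, validation_fraction=0.0))
    bad = Segment(np.zeros(L + 8), np.zeros(L + 8, dtype=int), FS, "P00", 0)
    with pytest.raises(ValueError, match="length"):
        predict(trained, [bad])


def test_svm_uses_decision_scores_as_probabilities():
    segs = _toy_segments()
    trained = fit(build(ModelSpec("svm"), L, seed=0), segs,
                  TrainConfig(epochs=1, validation_fraction=0.0))
    (tr,) = predict(trained, segs[:1])
    # the toy task is separable per amplitude, so the SVM should do well
    assert (tr.mask == segs[0].mask).mean() > 0.9
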