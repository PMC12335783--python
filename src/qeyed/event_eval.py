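"""Event-level evaluation of Quiet-Eye predictions.

Binary masks are scanned chronologically for 0→1 (onset) and 1→0 (offset)
transitions; predicted events are matched one-to-one to ground-truth events
of the same type under a time tolerance (100 ms by default). A matched
prediction is a true positive with a signed timing bias

    Bias_on  = t_on_pred  - t_on
    Bias_off = t_off_pred - t_off

an unmatched prediction is a false positive and an unmatched truth a false
negative. From pooled counts:

    PPV = TP / (TP + FP)        (precision)
    SEN = TP / (TP + FN)        (recall)
    F1  = 2 * PPV * SEN / (PPV + SEN)

plus per-sample accuracy and the mean absolute onset/offset error in ms.

Matching is order-preserving: among maximum-cardinality matchings within
tolerance it selects one of minimum total |bias| by dynamic programming
over the two chronologically sorted event lists. For symmetric tolerances
on a line an uncrossing argument shows a non-crossing maximum matching
always exists, so the DP is exactly optimal — verified in the test suite
against a brute-force bipartite oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .detectors import ModelSpec, TrainConfig, TrainedModel, build, fit, predict
from .segmenter import Segment

__all__ = [
    "EventList",
    "MatchReport",
    "MetricsReport",
    "clean_mask",
    "extract_events",
    "events_to_mask",
    "evaluate_masks",
    "match_events",
    "match_times",
    "compute_metrics",
    "cross_validate",
    "CrossValidationResult",
    "paired_compare",
]

UNDEFINED = float("nan")  # marker for metrics with zero denominator


@dataclass(frozen=True)
class EventList:
    """Chronologically ordered, non-overlapping (onset, offset) pairs in seconds."""

    events: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_off = -np.inf
        for on, off in self.events:
            if not on < off:
                raise ValueError(f"event onset {on} must precede offset {off}")
            if on < prev_off:
                raise ValueError("events must be chronological and non-overlapping")
            prev_off = off

    @property
    def onsets(self) -> list[float]:
        return [e[0] for e in self.events]

    @property
    def offsets(self) -> list[float]:
        return [e[1] for e in self.events]

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class MatchReport:
    """Tolerance-matched counts and per-match signed biases (seconds)."""

    tp_on: int = 0
    fp_on: int = 0
    fn_on: int = 0
    tp_off: int = 0
    fp_off: int = 0
    fn_off: int = 0
    onset_biases: list[float] = field(default_factory=list)
    offset_biases: list[float] = field(default_factory=list)
    tolerance: float = 0.1


@dataclass
class MetricsReport:
    """Pooled event metrics plus per-sample accuracy; NaN marks a metric whose
    denominator was zero (never silently reported as 0)."""

    accuracy: float
    ppv: float
    sen: float
    f1: float
    mae_onset_ms: float
    mae_offset_ms: float
    tp: int
    fp: int
    fn: int


def clean_mask(mask: np.ndarray, fs: float, min_gap_s: float = 0.1,
               min_event_s: float = 0.3) -> np.ndarray:
    """Morphological cleanup of a predicted QE mask.

    First closes 0-gaps shorter than ``min_gap_s`` (sub-tolerance flicker in
    the probability trace), then removes 1-runs shorter than ``min_event_s``:
    by definition a Quiet-Eye fixation lasts at least ~300 ms, so shorter
    candidate events cannot be QE. Ground-truth masks should not be cleaned.
    """
    m = np.asarray(mask).astype(np.int8).copy()
    pad = np.concatenate([[1], m, [1]])
    d = np.diff(pad)
    for a, b in zip(np.flatnonzero(d == -1), np.flatnonzero(d == 1)):
        if 0 < a and b < len(m) and (b - a) / fs < min_gap_s:
            m[a:b] = 1
    pad = np.concatenate([[0], m, [0]])
    d = np.diff(pad)
    for a, b in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if (b - a) / fs < min_event_s:
            m[a:b] = 0
    return m


def extract_events(mask: np.ndarray, fs: float) -> EventList:
    """Scan a 0/1 mask for transitions; runs touching a segment edge are
    clamped to the edge rather than dropped."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be 0/1 valued")
    m = m.astype(np.int8)
    padded = np.concatenate([[0], m, [0]])
    d = np.diff(padded)
    onsets = np.flatnonzero(d == 1) / fs
    offsets = np.flatnonzero(d == -1) / fs
    return EventList(tuple(zip(onsets.tolist(), offsets.tolist())))


def events_to_mask(events: EventList, length: int, fs: float) -> np.ndarray:
    """Inverse of :func:`extract_events` for events aligned to the sample grid."""
    mask = np.zeros(length, dtype=np.int8)
    eps = 1e-9
    for on, off in events.events:
        i0 = max(int(np.ceil(on * fs - eps)), 0)
        i1 = min(int(np.ceil(off * fs - eps)), length)
        mask[i0:i1] = 1
    return mask


def match_times(pred: Sequence[float], truth: Sequence[float], tolerance: float
                ) -> tuple[list[tuple[int, int]], list[float]]:
    """Match two sorted time lists one-to-one within ``tolerance``.

    Returns (pairs of (truth_index, pred_index), signed biases pred-truth).
    Maximizes the number of matches; among maximal matchings minimizes the
    total absolute bias.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    p = sorted(pred)
    t = sorted(truth)
    n, m = len(t), len(p)
    # dp over (i truths, j preds): value = (#matches, -total_bias), non-crossing
    NEG = (-1, 0.0)
    dp = [[(0, 0.0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(dp[i - 1][j], dp[i][j - 1])
            if abs(t[i - 1] - p[j - 1]) <= tolerance:
                c, cost = dp[i - 1][j - 1]
                cand = (c + 1, cost - abs(t[i - 1] - p[j - 1]))
                best = max(best, cand)
            dp[i][j] = best
    # backtrack
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if (abs(t[i - 1] - p[j - 1]) <= tolerance
                and dp[i][j] == (dp[i - 1][j - 1][0] + 1,
                                 dp[i - 1][j - 1][1] - abs(t[i - 1] - p[j - 1]))):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif dp[i][j] == dp[i - 1][j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    biases = [p[jj] - t[ii] for ii, jj in pairs]
    return pairs, biases


def match_events(pred: EventList, truth: EventList, tolerance: float = 0.1) -> MatchReport:
    """Match onsets and offsets independently under the tolerance rule."""
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    rep = MatchReport(tolerance=tolerance)
    on_pairs, on_biases = match_times(pred.onsets, truth.onsets, tolerance)
    off_pairs, off_biases = match_times(pred.offsets, truth.offsets, tolerance)
    rep.tp_on = len(on_pairs)
    rep.fp_on = len(pred.onsets) - rep.tp_on
    rep.fn_on = len(truth.onsets) - rep.tp_on
    rep.tp_off = len(off_pairs)
    rep.fp_off = len(pred.offsets) - rep.tp_off
    rep.fn_off = len(truth.offsets) - rep.tp_off
    rep.onset_biases = on_biases
    rep.offset_biases = off_biases
    return rep


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_metrics(matches: Sequence[MatchReport],
                    pred_masks: Sequence[np.ndarray],
                    truth_masks: Sequence[np.ndarray]) -> MetricsReport:
    """Pool TP/FP/FN (onsets and offsets together) across segments."""
    if not matches or len(pred_masks) != len(truth_masks) or not pred_masks:
        raise ValueError("need non-empty, aligned matches and mask lists")
    tp = sum(m.tp_on + m.tp_off for m in matches)
    fp = sum(m.fp_on + m.fp_off for m in matches)
    fn = sum(m.fn_on + m.fn_off for m in matches)
    ppv = _ratio(tp, tp + fp)
    sen = _ratio(tp, tp + fn)
    f1 = _ratio(2 * ppv * sen, ppv + sen) if np.isfinite(ppv) and np.isfinite(sen) else UNDEFINED
    total = correct = 0
    for pm, tm in zip(pred_masks, truth_masks):
        pm = np.asarray(pm); tm = np.asarray(tm)
        if pm.shape != tm.shape:
            raise ValueError("prediction/truth mask length mismatch")
        correct += int((pm == tm).sum())
        total += pm.size
    on_b = [b for m in matches for b in m.onset_biases]
    off_b = [b for m in matches for b in m.offset_biases]
    return MetricsReport(
        accuracy=correct / total,
        ppv=ppv, sen=sen, f1=f1,
        mae_onset_ms=float(np.mean(np.abs(on_b)) * 1000) if on_b else UNDEFINED,
        mae_offset_ms=float(np.mean(np.abs(off_b)) * 1000) if off_b else UNDEFINED,
        tp=tp, fp=fp, fn=fn,
    )


def evaluate_masks(pred_masks: Sequence[np.ndarray], truth_masks: Sequence[np.ndarray],
                   fs: float, tolerance: float = 0.1, min_event_s: float = 0.3,
                   min_gap_s: float = 0.1) -> MetricsReport:
    """Clean predicted masks (:func:`clean_mask`), extract events from both
    sides, match within tolerance and pool metrics. Set ``min_event_s`` and
    ``min_gap_s`` to 0 to evaluate raw thresholded masks."""
    cleaned = [clean_mask(pm, fs, min_gap_s, min_event_s) for pm in pred_masks]
    matches = [
        match_events(extract_events(pm, fs), extract_events(tm, fs), tolerance)
        for pm, tm in zip(cleaned, truth_masks)
    ]
    return compute_metrics(matches, cleaned, truth_masks)


@dataclass
class CrossValidationResult:
    """Per-fold metrics plus their mean/sd summary (Table-style aggregation)."""

    per_fold: list[MetricsReport]
    summary: dict[str, tuple[float, float]]  # metric -> (mean, sd)

    def fold_values(self, metric: str) -> list[float]:
        return [getattr(r, metric) for r in self.per_fold]


def _summarize(per_fold: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    out = {}
    for name in ("accuracy", "ppv", "sen", "f1", "mae_onset_ms", "mae_offset_ms"):
        vals = np.array([getattr(r, name) for r in per_fold], dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size:
            out[name] = (float(finite.mean()), float(finite.std(ddof=1)) if finite.size > 1 else 0.0)
        else:
            out[name] = (UNDEFINED, UNDEFINED)
    return out


def cross_validate(segments: Sequence[Segment],
                   folds: Sequence[tuple[np.ndarray, np.ndarray]],
                   spec: ModelSpec,
                   cfg: TrainConfig = TrainConfig(),
                   tolerance: float = 0.1,
                   min_event_s: float = 0.3,
                   min_gap_s: float = 0.1) -> CrossValidationResult:
    """Train/evaluate a detector over pre-built folds.

    Augmented copies in a test split are excluded from evaluation (they are
    training aids, not observations); they do participate in training.
    Per-fold seeds are derived from ``cfg.seed`` so folds are independent
    but the whole run is reproducible.
    """
    per_fold: list[MetricsReport] = []
    for k, (train_idx, test_idx) in enumerate(folds):
        train_set = [segments[i] for i in train_idx]
        test_set = [segments[i] for i in test_idx if not segments[i].augmented]
        fold_cfg = replace(cfg, seed=(cfg.seed + k) % 2**31)
        model = build(spec, len(train_set[0].samples), seed=fold_cfg.seed)
        trained = fit(model, train_set, fold_cfg)
        traces = predict(trained, test_set)
        fs = test_set[0].fs
        per_fold.append(evaluate_masks([t.mask for t in traces],
                                       [s.mask for s in test_set], fs, tolerance,
                                       min_event_s, min_gap_s))
    return CrossValidationResult(per_fold, _summarize(per_fold))


def paired_compare(metrics_a: Sequence[float], metrics_b: Sequence[float]
                   ) -> tuple[float, float]:
    """Two-sided paired t-test on fold-wise metric values.

    Returns (t, p). All-zero differences give t = 0, p = 1; constant nonzero
    differences have zero variance and yield the NaN undefined-marker.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples with length >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        return UNDEFINED, UNDEFINED
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
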