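"""Event extraction, tolerance matching (vs brute-force oracle) and metrics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qeyed.event_eval import (
    EventList,
    MatchReport,
    clean_mask,
    compute_metrics,
    events_to_mask,
    extract_events,
    match_events,
    match_times,
    paired_compare,
)


# --- event extraction -------------------------------------------------------

def test_all_zero_mask_has_no_events():
    assert len(extract_events(np.zeros(100, dtype=int), 200.0)) == 0


def test_known_run_maps_to_seconds():
    mask = np.zeros(1700, dtype=int)
    mask[500:900] = 1
    ev = extract_events(mask, 200.0)
    assert ev.events == ((2.5, 4.5),)


def test_runs_touching_edges_are_clamped():
    mask = np.ones(10, dtype=int)
    ev = extract_events(mask, 10.0)
    assert ev.events == ((0.0, 1.0),)


def test_non_binary_mask_rejected():
    with pytest.raises(ValueError, match="0/1"):
        extract_events(np.array([0, 2, 1]), 10.0)


def _runs_oracle(mask):
    """Brute-force run-length scanner used as the round-trip oracle."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        if not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
def test_mask_event_roundtrip_matches_run_scanner(bits):
    mask = np.array(bits, dtype=int)
    fs = 200.0
    ev = extract_events(mask, fs)
    assert [(round(a * fs), round(b * fs)) for a, b in ev.events] == _runs_oracle(bits)
    np.testing.assert_array_equal(events_to_mask(ev, len(bits), fs), mask)


def test_eventlist_validates_ordering():
    with pytest.raises(ValueError):
        EventList(((1.0, 0.5),))
    with pytest.raises(ValueError):
        EventList(((0.0, 2.0), (1.0, 3.0)))


def test_clean_mask_fills_gaps_then_drops_short_runs():
    fs = 100.0
    mask = np.zeros(200, dtype=int)
    mask[50:80] = 1   # 0.3 s run
    mask[83:120] = 1  # 0.03 s gap -> closed
    mask[150:155] = 1  # 0.05 s blip -> dropped
    out = clean_mask(mask, fs, min_gap_s=0.1, min_event_s=0.3)
    assert _runs_oracle(out.tolist()) == [(50, 120)]


# --- tolerance matching -----------------------------------------------------

def _oracle_match(pred, truth, tol):
    """Exhaustive maximum-cardinality, then min-total-|bias| matching."""
    best = (0, 0.0)
    for k in range(min(len(pred), len(truth)), -1, -1):
        found = None
        for t_sub in itertools.combinations(range(len(truth)), k):
            for p_sub in itertools.permutations(range(len(pred)), k):
                if all(abs(truth[t] - pred[p]) <= tol for t, p in zip(t_sub, p_sub)):
                    cost = sum(abs(truth[t] - pred[p]) for t, p in zip(t_sub, p_sub))
                    if found is None or cost < found:
                        found = cost
        if found is not None:
            return k, found
    return 0, 0.0


def test_exact_agreement_is_all_tp_zero_bias():
    ev = EventList(((1.0, 2.0), (3.0, 4.0)))
    rep = match_events(ev, ev, 0.1)
    assert (rep.tp_on, rep.fp_on, rep.fn_on) == (2, 0, 0)
    assert (rep.tp_off, rep.fp_off, rep.fn_off) == (2, 0, 0)
    assert rep.onset_biases == [0.0, 0.0] and rep.offset_biases == [0.0, 0.0]


def test_known_bias_recorded():
    rep = match_events(EventList(((2.58, 5.0),)), EventList(((2.5, 5.0),)), 0.1)
    assert rep.tp_on == 1
    assert rep.onset_biases[0] == pytest.approx(0.08)


def test_out_of_tolerance_is_fp_plus_fn():
    rep = match_events(EventList(((2.8, 5.0),)), EventList(((2.5, 5.0),)), 0.1)
    assert (rep.tp_on, rep.fp_on, rep.fn_on) == (0, 1, 1)


def test_negative_tolerance_rejected():
    with pytest.raises(ValueError):
        match_events(EventList(()), EventList(()), -0.1)


def test_nearest_neighbour_counterexample_is_handled_optimally():
    # a greedy nearest-neighbour matcher would find only one pair here
    pairs, biases = match_times([-0.09, 0.04], [0.0, 0.08], 0.1)
    assert len(pairs) == 2


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0, 10, allow_nan=False), min_size=0, max_size=5),
    st.lists(st.floats(0, 10, allow_nan=False), min_size=0, max_size=5),
    st.floats(0.01, 2.0, allow_nan=False),
)
def test_matching_equals_exhaustive_oracle(pred, truth, tol):
    pairs, biases = match_times(pred, truth, tol)
    k, cost = _oracle_match(sorted(pred), sorted(truth), tol)
    assert len(pairs) == k
    assert sum(abs(b) for b in biases) <= cost + 1e-9
    assert all(abs(b) <= tol + 1e-12 for b in biases)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0, 10, allow_nan=False), min_size=0, max_size=5),
    st.lists(st.floats(0, 10, allow_nan=False), min_size=0, max_size=5),
    st.floats(0.01, 1.0, allow_nan=False),
)
def test_tolerance_monotonicity(pred, truth, tol):
    n1, _ = match_times(pred, truth, tol)
    n2, _ = match_times(pred, truth, 2 * tol)
    assert len(n2) >= len(n1)


def test_count_conservation():
    pred = EventList(((1.0, 2.0), (4.0, 4.5), (6.0, 7.0)))
    truth = EventList(((1.05, 2.2), (5.9, 7.2)))
    rep = match_events(pred, truth, 0.1)
    assert rep.tp_on + rep.fp_on == 3
    assert rep.tp_on + rep.fn_on == 2
    assert rep.tp_off + rep.fp_off == 3
    assert rep.tp_off + rep.fn_off == 2


# --- metrics ----------------------------------------------------------------

def _mask(n, runs):
    m = np.zeros(n, dtype=int)
    for a, b in runs:
        m[a:b] = 1
    return m


def test_perfect_prediction_metrics():
    truth = _mask(100, [(10, 40)])
    rep = match_events(extract_events(truth, 10.0), extract_events(truth, 10.0), 0.1)
    out = compute_metrics([rep], [truth], [truth])
    assert out.accuracy == out.ppv == out.sen == out.f1 == 1.0
    assert out.mae_onset_ms == 0.0 and out.mae_offset_ms == 0.0


def test_pooled_closed_forms():
    # pooled TP=3, FP=1, FN=2 split across onset/offset slots
    rep = MatchReport(tp_on=2, fp_on=1, fn_on=1, tp_off=1, fp_off=0, fn_off=1,
                      onset_biases=[0.02, -0.04], offset_biases=[0.06])
    m = _mask(10, [(2, 5)])
    out = compute_metrics([rep], [m], [m])
    assert out.ppv == pytest.approx(0.75)
    assert out.sen == pytest.approx(0.6)
    assert out.f1 == pytest.approx(2 / 3)
    assert out.mae_onset_ms == pytest.approx(30.0)
    assert out.mae_offset_ms == pytest.approx(60.0)


def test_mae_is_mean_absolute_bias():
    rep = MatchReport(tp_on=3, onset_biases=[0.02, -0.04, 0.06])
    m = _mask(4, [(1, 2)])
    out = compute_metrics([rep], [m], [m])
    assert out.mae_onset_ms == pytest.approx(40.0)


def test_zero_denominator_marks_undefined():
    rep = MatchReport()  # no events anywhere
    m = np.zeros(5, dtype=int)
    out = compute_metrics([rep], [m], [m])
    assert math.isnan(out.ppv) and math.isnan(out.sen) and math.isnan(out.f1)
    assert out.accuracy == 1.0


def test_f1_harmonic_identity_on_random_counts():
    rng = np.random.default_rng(0)
    for _ in range(50):
        tp, fp, fn = rng.integers(0, 10, 3)
        rep = MatchReport(tp_on=int(tp), fp_on=int(fp), fn_on=int(fn))
        m = _mask(4, [(1, 2)])
        out = compute_metrics([rep], [m], [m])
        if np.isfinite(out.f1):
            assert out.f1 == pytest.approx(2 * out.ppv * out.sen / (out.ppv + out.sen))
            assert 0 <= out.f1 <= 1


# --- paired comparison ------------------------------------------------------

def test_identical_inputs_give_t_zero():
    t, p = paired_compare([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
    assert t == 0.0 and p == 1.0


def test_constant_nonzero_difference_is_undefined():
    t, p = paired_compare([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
    assert math.isnan(t) and math.isnan(p)


def test_hand_computed_t_statistic():
    t, p = paired_compare([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
    assert t == pytest.approx(2 * math.sqrt(3), rel=1e-9)
    assert 0 < p < 0.1


def test_short_inputs_rejected():
    with pytest.raises(ValueError):
        paired_compare([1.0], [0.0])
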