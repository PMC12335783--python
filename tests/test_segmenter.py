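"""Windowing, masks, augmentation and participant-grouped folds."""

import logging

import numpy as np
import pytest

from qeyed.segmenter import AugmentSpec, Segment, WindowSpec, augment, extract_segments, make_folds
from qeyed.sim import EOGRecording, QEAnnotation, SimConfig, simulate_cohort


def _rec(fs=200.0, dur=30.0, anns=(), pid="P01"):
    return EOGRecording(samples=np.zeros(int(dur * fs)), fs=fs, participant_id=pid,
                        annotations=[QEAnnotation(i, a, b) for i, (a, b) in enumerate(anns)])


def test_window_length_is_1700_at_defaults():
    assert WindowSpec().length(200.0) == 1700


def test_every_segment_has_window_length(small_cohort):
    for rec in small_cohort:
        for seg in extract_segments(rec):
            assert seg.samples.size == seg.mask.size == 1700


def test_mask_sum_matches_duration():
    rec = _rec(anns=[(5.0, 7.0)])
    (seg,) = extract_segments(rec)
    assert abs(int(seg.mask.sum()) - 400) <= 1


def test_mask_position_is_onset_anchored():
    rec = _rec(anns=[(5.0, 7.0)])
    (seg,) = extract_segments(rec)
    ones = np.flatnonzero(seg.mask)
    assert ones[0] == 500  # 2.5 s of pre-onset context at 200 Hz
    assert ones[-1] - ones[0] + 1 == ones.size  # contiguous run


def test_window_preceding_start_is_skipped(caplog):
    rec = _rec(anns=[(1.0, 2.0), (10.0, 11.0)])
    with caplog.at_level(logging.WARNING):
        segs = extract_segments(rec)
    assert len(segs) == 1
    assert "skipping shot" in caplog.text


def test_window_past_end_is_skipped():
    rec = _rec(dur=12.0, anns=[(8.0, 9.0)])
    assert extract_segments(rec) == []


def test_null_augmentation_copies_identical():
    rec = _rec(anns=[(5.0, 7.0)])
    segs = extract_segments(rec)
    out = augment(segs, AugmentSpec(max_shift_s=0.0, noise_sd=0.0, copies_per_segment=1))
    assert len(out) == 2
    np.testing.assert_array_equal(out[0].samples, out[1].samples)
    np.testing.assert_array_equal(out[0].mask, out[1].mask)
    assert not out[0].augmented and out[1].augmented


def test_shift_preserves_mask_run_length_and_contiguity():
    rec = _rec(anns=[(5.0, 7.0)])
    segs = extract_segments(rec)
    out = augment(segs, AugmentSpec(max_shift_s=0.5, noise_sd=0.0, copies_per_segment=8, seed=3))
    for seg in out:
        assert int(seg.mask.sum()) == int(segs[0].mask.sum())
        ones = np.flatnonzero(seg.mask)
        assert ones[-1] - ones[0] + 1 == ones.size


def test_noise_augmentation_touches_samples_not_mask():
    rec = _rec(anns=[(5.0, 7.0)])
    (seg,) = extract_segments(rec)
    seg = Segment(np.sin(np.arange(1700) / 7.0), seg.mask, seg.fs, "P01", 0)
    out = augment([seg], AugmentSpec(max_shift_s=0.0, noise_sd=0.1, relative_noise=False,
                                     copies_per_segment=1, seed=5))
    aug = out[1]
    np.testing.assert_array_equal(aug.mask, seg.mask)
    diff = aug.samples - seg.samples
    assert diff.std() > 0
    assert abs(diff.mean()) < 3 * 0.1 / np.sqrt(1700)


def test_augmentation_deterministic_under_seed():
    rec = _rec(anns=[(5.0, 7.0)])
    segs = extract_segments(rec)
    spec = AugmentSpec(copies_per_segment=2, seed=9)
    a = augment(segs, spec)
    b = augment(segs, spec)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.samples, y.samples)


def test_folds_partition_is_disjoint_and_exhaustive():
    cohort = simulate_cohort(SimConfig(n_shots=6, seed=1), 10)
    segs = [s for r in cohort for s in extract_segments(r)]
    folds = make_folds(segs, 5, seed=0)
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test.tolist()) == list(range(len(segs)))
    for tr, te in folds:
        assert set(tr) & set(te) == set()
        assert len(te) == 12  # 60 segments over 5 balanced folds


def test_folds_group_by_participant():
    cohort = simulate_cohort(SimConfig(n_shots=3, seed=2), 6)
    segs = [s for r in cohort for s in extract_segments(r)]
    folds = make_folds(segs, 3, seed=1)
    for tr, te in folds:
        train_p = {segs[i].participant_id for i in tr}
        test_p = {segs[i].participant_id for i in te}
        assert train_p & test_p == set()


def test_augmented_copies_follow_parent_fold():
    cohort = simulate_cohort(SimConfig(n_shots=3, seed=2), 4)
    segs = [s for r in cohort for s in extract_segments(r)]
    segs = augment(segs, AugmentSpec(copies_per_segment=1, seed=0))
    folds = make_folds(segs, 2, seed=0)
    for _, te in folds:
        test_p = {segs[i].participant_id for i in te}
        # every segment of a test participant (augmented or not) is in the fold
        expected = [i for i, s in enumerate(segs) if s.participant_id in test_p]
        assert sorted(te.tolist()) == expected


def test_too_few_groups_raises():
    cohort = simulate_cohort(SimConfig(n_shots=2, seed=3), 2)
    segs = [s for r in cohort for s in extract_segments(r)]
    with pytest.raises(ValueError, match="k <="):
        make_folds(segs, 5)


def test_mask_must_be_binary():
    with pytest.raises(ValueError, match="0/1"):
        Segment(np.zeros(10), np.full(10, 2), 200.0, "P01", 0)
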