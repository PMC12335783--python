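"""Windowing annotated recordings into fixed-length training segments.

Each annotated shot yields one window anchored at the QE onset, spanning
2.5 s before to 6 s after it — 8.5 s, i.e. exactly 1700 samples at 200 Hz —
paired with a per-sample binary mask (1 inside the QE interval). Sample
``i`` of a recording covers the half-open time slot ``[i/fs, (i+1)/fs)`` and
intervals are half-open ``[t_on, t_off)``, which makes mask sums and
mask↔event round trips exact.

Augmentation (circular time shifts applied jointly to samples and mask, plus
low-intensity Gaussian noise on the samples only) and participant-grouped
k-fold splitting live here too. Folds are grouped by participant so that no
participant contributes to both the train and the test side of a fold — the
leakage that plagues small biosignal cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sim import EOGRecording

__all__ = [
    "WindowSpec",
    "AugmentSpec",
    "Segment",
    "extract_segments",
    "augment",
    "make_folds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window relative to QE onset: ``[t_on - pre_s, t_on + post_s)``."""

    pre_s: float = 2.5
    post_s: float = 6.0

    def __post_init__(self) -> None:
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ValueError("pre_s and post_s must be positive")

    def length(self, fs: float) -> int:
        """Window length in samples (1700 at the 200 Hz defaults)."""
        return int(round((self.pre_s + self.post_s) * fs))


@dataclass(frozen=True)
class AugmentSpec:
    """Augmentation settings.

    max_shift_s : largest circular time shift, seconds (both directions).
    noise_sd : Gaussian noise sd in µV; if ``relative_noise`` is true it is
        instead a fraction of each segment's sample standard deviation.
    copies_per_segment : augmented copies generated per original segment.
    """

    max_shift_s: float = 0.25
    noise_sd: float = 0.05
    relative_noise: bool = True
    copies_per_segment: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_shift_s < 0 or self.noise_sd < 0 or self.copies_per_segment < 0:
            raise ValueError("augmentation magnitudes must be non-negative")


@dataclass
class Segment:
    """A fixed-length window of samples with its per-sample binary QE mask."""

    samples: np.ndarray
    mask: np.ndarray
    fs: float
    participant_id: str
    shot_id: int
    augmented: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.samples.shape != self.mask.shape or self.samples.ndim != 1:
            raise ValueError("samples and mask must be 1-D arrays of equal length")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be 0/1 valued")
        self.mask = self.mask.astype(np.int8)

    @property
    def source(self) -> tuple[str, int]:
        return (self.participant_id, self.shot_id)


def _mask_for(t_on: float, t_off: float, start_idx: int, L: int, fs: float) -> np.ndarray:
    """1 exactly on window-local indices whose time slot start lies in [t_on, t_off)."""
    mask = np.zeros(L, dtype=np.int8)
    eps = 1e-9
    i0 = int(np.ceil(t_on * fs - eps))
    i1 = int(np.ceil(t_off * fs - eps))
    lo = max(i0 - start_idx, 0)
    hi = min(i1 - start_idx, L)
    if hi > lo:
        mask[lo:hi] = 1
    return mask


def extract_segments(recording: EOGRecording, win: WindowSpec = WindowSpec()) -> list[Segment]:
    """Cut one onset-anchored window per annotation.

    Shots whose window would extend past either edge of the recording are
    skipped with a logged warning rather than zero-padded, so every emitted
    segment is genuine signal.
    """
    fs = recording.fs
    L = win.length(fs)
    n = recording.samples.size
    out: list[Segment] = []
    skipped = 0
    for a in recording.annotations:
        start = int(round((a.t_on - win.pre_s) * fs))
        if start < 0 or start + L > n:
            skipped += 1
            logger.warning(
                "skipping shot %s of %s: window [%d, %d) outside recording of %d samples",
                a.shot_id, recording.participant_id, start, start + L, n,
            )
            continue
        out.append(
            Segment(
                samples=recording.samples[start : start + L].copy(),
                mask=_mask_for(a.t_on, a.t_off, start, L, fs),
                fs=fs,
                participant_id=recording.participant_id,
                shot_id=a.shot_id,
            )
        )
    if skipped:
        logger.warning("%d/%d shots skipped for %s", skipped, len(recording.annotations),
                       recording.participant_id)
    return out


def _mask_run_intact(mask: np.ndarray) -> bool:
    """True if the 1-run is a single contiguous block not touching both edges."""
    ones = np.flatnonzero(mask)
    if ones.size == 0:
        return True
    contiguous = ones[-1] - ones[0] + 1 == ones.size
    wraps = bool(mask[0] and mask[-1])
    return contiguous and not wraps


def augment(segments: list[Segment], spec: AugmentSpec = AugmentSpec()) -> list[Segment]:
    """Originals plus seeded augmented copies.

    Shifts roll samples and mask together (so QE duration in samples is
    preserved); noise perturbs samples only. A shift that would split the QE
    run across the segment edge is resampled a bounded number of times, then
    the copy is skipped with a warning.
    """
    if not segments:
        raise ValueError("segments must be non-empty")
    rng = np.random.default_rng(spec.seed)
    out = list(segments)
    for seg in segments:
        max_shift = int(round(spec.max_shift_s * seg.fs))
        sd = spec.noise_sd * seg.samples.std() if spec.relative_noise else spec.noise_sd
        for _ in range(spec.copies_per_segment):
            for _attempt in range(16):
                shift = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
                mask = np.roll(seg.mask, shift)
                if _mask_run_intact(mask):
                    break
            else:
                logger.warning("could not shift %s without splitting the QE run; copy skipped",
                               seg.source)
                continue
            samples = np.roll(seg.samples, shift)
            if sd > 0:
                samples = samples + rng.normal(0.0, sd, size=samples.size)
            out.append(
                Segment(samples=samples, mask=mask, fs=seg.fs,
                        participant_id=seg.participant_id, shot_id=seg.shot_id, augmented=True)
            )
    return out


def make_folds(
    segments: list[Segment], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Participant-grouped k-fold partition.

    Participants are shuffled (seeded) and dealt to folds so that segment
    counts stay balanced; every segment lands in exactly one test fold, and
    augmented copies always share their parent's fold because they share its
    participant.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups = sorted({s.participant_id for s in segments})
    if len(groups) < k:
        raise ValueError(
            f"only {len(groups)} participant groups for k={k} folds; use k <= {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    order = [groups[i] for i in rng.permutation(len(groups))]
    fold_of_group: dict[str, int] = {}
    fold_sizes = np.zeros(k, dtype=int)
    counts = {g: sum(1 for s in segments if s.participant_id == g) for g in groups}
    for g in order:  # greedy balance: next group to the currently smallest fold
        f = int(np.argmin(fold_sizes))
        fold_of_group[g] = f
        fold_sizes[f] += counts[g]
    idx = np.arange(len(segments))
    folds = []
    for f in range(k):
        test = np.array([i for i in idx if fold_of_group[segments[i].participant_id] == f])
        train = np.array([i for i in idx if fold_of_group[segments[i].participant_id] != f])
        folds.append((train, test))
    return folds
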