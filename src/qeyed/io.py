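"""Plain-text serialization for recordings, annotations, segments and reports.

Everything is delimited text so artifacts stay diffable and portable:

* recording: ``<participant>.eog.tsv`` — ``#``-prefixed header lines
  (``fs``, ``channel``, ``participant_id``, optional provenance keys)
  followed by one amplitude (µV) per line.
* annotations: ``<participant>.qe.tsv`` — TSV of shot_id / t_on / t_off,
  times in seconds to 6 decimal places.
* segment store: ``samples.tsv`` + ``masks.tsv`` (one row per segment) and
  ``meta.tsv`` (participant, shot, augmented flag, fold assignment).
* reports: ``metrics.tsv`` / ``mae.tsv`` tables plus ``summary.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .event_eval import CrossValidationResult
from .segmenter import Segment
from .sim import EOGRecording, QEAnnotation

__all__ = [
    "write_recording",
    "read_recording",
    "write_segments",
    "read_segments",
    "write_report",
]


def write_recording(rec: EOGRecording, out_dir: str | Path,
                    extra_header: Mapping[str, str] | None = None) -> tuple[Path, Path]:
    """Write ``<participant>.eog.tsv`` and ``<participant>.qe.tsv``; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig = out_dir / f"{rec.participant_id}.eog.tsv"
    ann = out_dir / f"{rec.participant_id}.qe.tsv"
    with open(sig, "w") as fh:
        fh.write(f"# fs: {rec.fs}\n# channel: {rec.channel}\n")
        fh.write(f"# participant_id: {rec.participant_id}\n")
        for key, val in (extra_header or {}).items():
            fh.write(f"# {key}: {val}\n")
        np.savetxt(fh, rec.samples, fmt="%.6f")
    with open(ann, "w") as fh:
        fh.write("shot_id\tt_on\tt_off\n")
        for a in rec.annotations:
            fh.write(f"{a.shot_id}\t{a.t_on:.6f}\t{a.t_off:.6f}\n")
    return sig, ann


def read_recording(signal_path: str | Path, ann_path: str | Path | None = None) -> EOGRecording:
    """Inverse of :func:`write_recording`. If ``ann_path`` is omitted, the
    companion ``.qe.tsv`` next to the signal file is used when present."""
    signal_path = Path(signal_path)
    header: dict[str, str] = {}
    samples = []
    with open(signal_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
            else:
                samples.append(float(line))
    if ann_path is None:
        cand = signal_path.with_name(signal_path.name.replace(".eog.tsv", ".qe.tsv"))
        ann_path = cand if cand.exists() else None
    annotations = []
    if ann_path is not None:
        df = pd.read_csv(ann_path, sep="\t")
        annotations = [
            QEAnnotation(int(r.shot_id), float(r.t_on), float(r.t_off))
            for r in df.itertuples()
        ]
    return EOGRecording(
        samples=np.asarray(samples),
        fs=float(header["fs"]),
        channel=header.get("channel", "horizontal"),
        participant_id=header.get("participant_id", signal_path.stem.split(".")[0]),
        annotations=annotations,
    )


def write_segments(segments: Sequence[Segment], out_dir: str | Path,
                   folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "samples.tsv", np.stack([s.samples for s in segments]),
               fmt="%.6f", delimiter="\t")
    np.savetxt(out_dir / "masks.tsv", np.stack([s.mask for s in segments]),
               fmt="%d", delimiter="\t")
    fold_of = np.full(len(segments), -1)
    if folds is not None:
        for k, (_, test_idx) in enumerate(folds):
            fold_of[np.asarray(test_idx, dtype=int)] = k
    meta = pd.DataFrame({
        "participant_id": [s.participant_id for s in segments],
        "shot_id": [s.shot_id for s in segments],
        "fs": [s.fs for s in segments],
        "augmented": [int(s.augmented) for s in segments],
        "fold": fold_of,
    })
    meta.to_csv(out_dir / "meta.tsv", sep="\t", index=False)
    return out_dir


def read_segments(in_dir: str | Path) -> tuple[list[Segment], np.ndarray]:
    """Returns (segments, fold assignment per segment; -1 where unassigned)."""
    in_dir = Path(in_dir)
    samples = np.atleast_2d(np.loadtxt(in_dir / "samples.tsv", delimiter="\t"))
    masks = np.atleast_2d(np.loadtxt(in_dir / "masks.tsv", delimiter="\t", dtype=int))
    meta = pd.read_csv(in_dir / "meta.tsv", sep="\t")
    segs = [
        Segment(samples=samples[i], mask=masks[i], fs=float(meta.fs[i]),
                participant_id=str(meta.participant_id[i]), shot_id=int(meta.shot_id[i]),
                augmented=bool(meta.augmented[i]))
        for i in range(len(meta))
    ]
    return segs, meta["fold"].to_numpy()


def _fmt(mean: float, sd: float) -> str:
    return f"{mean:.3f} ± {sd:.3f}" if np.isfinite(mean) else "undefined"


def write_report(results: Mapping[tuple[str, str], CrossValidationResult],
                 out_dir: str | Path, config_hash: str = "") -> Path:
    """Write scenario × model tables: event metrics, timing MAE, JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, mae_rows, summary = [], [], {}
    for (scenario, family), res in sorted(results.items()):
        s = res.summary
        rows.append({
            "scenario": scenario, "model": family,
            "accuracy": f"{s['accuracy'][0]:.3f}",
            "ppv": _fmt(*s["ppv"]), "sen": _fmt(*s["sen"]), "f1": _fmt(*s["f1"]),
        })
        mae_rows.append({
            "scenario": scenario, "model": family,
            "onset_mae_ms": f"{s['mae_onset_ms'][0]:.1f}",
            "offset_mae_ms": f"{s['mae_offset_ms'][0]:.1f}",
        })
        summary[f"{scenario}/{family}"] = {
            metric: {"mean": s[metric][0], "sd": s[metric][1]} for metric in s
        } | {"per_fold_f1": res.fold_values("f1")}
    pd.DataFrame(rows).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    pd.DataFrame(mae_rows).to_csv(out_dir / "mae.tsv", sep="\t", index=False)
    payload = {"config_hash": config_hash, "results": summary}
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True,
                                                     allow_nan=True) + "\n")
    return out_dir
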