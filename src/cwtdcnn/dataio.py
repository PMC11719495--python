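"""Segment and manifest I/O plus train/eval splitting.

Canonical on-disk layout
------------------------
* One CSV per segment: T rows x 35 columns, header = channel names
  (``ch00``..``ch34``), full float precision.
* A JSON sidecar ``<segment>.json`` next to each CSV holding the sampling
  rate and identity (fs, label, subject_id, segment_id).
* A tab-separated manifest with one row per segment
  (subject_id, segment_id, label, path).

An EDF reader (first 35 signals, first full second) is available as an
optional adapter when ``mne`` is installed; the CSV path is canonical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CLASS_NAMES, EEGSegment

__all__ = [
    "SplitSpec",
    "write_segment",
    "read_segment",
    "write_manifest",
    "read_manifest",
    "split_dataset",
    "split_three_way",
]

N_CHANNELS_EXPECTED = 35


@dataclass(frozen=True)
class SplitSpec:
    """Train/eval split policy.

    ``mode='segment'`` permutes segments uniformly and sends the first
    ceil(train_fraction * N) to the training partition — the protocol used
    by the study this pipeline reproduces, where the held-out 25% serves as
    both validation and test. ``mode='subject'`` assigns whole subjects
    (permuted within class) so no subject spans both partitions; it avoids
    subject-level leakage at the cost of protocol fidelity.
    """

    train_fraction: float = 0.75
    mode: str = "segment"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode not in ("segment", "subject"):
            raise ValueError("mode must be 'segment' or 'subject'")


def _channel_names(n: int) -> list[str]:
    return [f"ch{i:02d}" for i in range(n)]


def write_segment(path: str | Path, segment: EEGSegment) -> Path:
    """Write one segment as CSV (T rows x C columns) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(segment.samples.T, columns=_channel_names(segment.n_channels))
    frame.to_csv(path, index=False)
    sidecar = {
        "fs": segment.fs,
        "label": int(segment.label),
        "subject_id": segment.subject_id,
        "segment_id": segment.segment_id,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))
    return path


def read_segment(
    path: str | Path,
    format: str = "csv",
    n_channels: int = N_CHANNELS_EXPECTED,
) -> EEGSegment:
    """Read one labelled segment.

    ``format='csv'`` reads the canonical CSV + sidecar pair. ``format='edf'``
    reads the first ``n_channels`` signals and the first full second of an
    EDF recording via :mod:`mne` (optional dependency); EDF files carry no
    class label, so ``label`` defaults to 0 and callers relabel from their
    own metadata.
    """
    path = Path(path)
    if format == "csv":
        frame = pd.read_csv(path)
        if frame.shape[1] != n_channels:
            raise ValueError(
                f"{path}: expected {n_channels} channels, found {frame.shape[1]}"
            )
        samples = frame.to_numpy(dtype=np.float64).T
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"{path}: non-finite sample values")
        meta = json.loads(Path(str(path) + ".json").read_text())
        return EEGSegment(
            samples=samples,
            fs=float(meta["fs"]),
            label=int(meta["label"]),
            subject_id=str(meta["subject_id"]),
            segment_id=str(meta["segment_id"]),
        )
    if format == "edf":
        return _read_segment_edf(path, n_channels)
    raise ValueError(f"unknown segment format: {format!r}")


def _read_segment_edf(path: Path, n_channels: int) -> EEGSegment:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if len(raw.ch_names) < n_channels:
        raise ValueError(
            f"{path}: expected >= {n_channels} signals, found {len(raw.ch_names)}"
        )
    fs = float(raw.info["sfreq"])
    t = int(round(fs))
    data = raw.get_data(picks=raw.ch_names[:n_channels], start=0, stop=t)
    if data.shape[1] < t:
        raise ValueError(f"{path}: recording shorter than 1 s")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite sample values")
    return EEGSegment(
        samples=data,
        fs=fs,
        label=0,
        subject_id=path.stem,
        segment_id="s000",
    )


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "segment_id": str})
    required = {"subject_id", "segment_id", "label"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dupes = manifest.duplicated(subset=["subject_id", "segment_id"])
    if dupes.any():
        raise ValueError("manifest has duplicate (subject_id, segment_id) pairs")
    return manifest


def split_dataset(
    manifest: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a manifest into (train, eval) per ``spec``.

    Segment mode: uniform random permutation of rows, first
    ceil(train_fraction * N) to train. Subject mode: subjects permuted
    within class and assigned to train until that class's train fraction is
    reached; requires >= 2 subjects per class so both partitions are
    non-empty. Deterministic given ``spec.seed``.
    """
    if len(manifest) == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "segment":
        order = rng.permutation(len(manifest))
        n_train = math.ceil(spec.train_fraction * len(manifest))
        train_idx, eval_idx = order[:n_train], order[n_train:]
        return (
            manifest.iloc[np.sort(train_idx)].reset_index(drop=True),
            manifest.iloc[np.sort(eval_idx)].reset_index(drop=True),
        )

    # subject mode
    return _split_subjects(manifest, spec, rng)


def split_three_way(
    manifest: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Optional (train, validation, test) split.

    The default protocol uses one 25% partition for both validation and
    test; this variant halves that partition deterministically (first half
    validation, second half test, in permuted order) for workflows that
    want early stopping on data disjoint from the final test set.
    """
    train, held_out = split_dataset(manifest, spec)
    rng = np.random.default_rng(spec.seed + 1)
    order = rng.permutation(len(held_out))
    half = len(held_out) // 2
    val_idx, test_idx = order[:half], order[half:]
    return (
        train,
        held_out.iloc[np.sort(val_idx)].reset_index(drop=True),
        held_out.iloc[np.sort(test_idx)].reset_index(drop=True),
    )


def _split_subjects(
    manifest: pd.DataFrame, spec: SplitSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    train_subjects: list[str] = []
    for label in sorted(manifest["label"].unique()):
        subjects = manifest.loc[manifest["label"] == label, "subject_id"].unique()
        if len(subjects) < 2:
            raise ValueError(
                f"subject-mode split needs >= 2 subjects per class "
                f"(class {CLASS_NAMES[label] if label < len(CLASS_NAMES) else label})"
            )
        counts = (
            manifest[manifest["label"] == label]
            .groupby("subject_id")
            .size()
            .reindex(subjects)
        )
        order = rng.permutation(len(subjects))
        target = spec.train_fraction * counts.sum()
        taken = 0
        n_added = 0
        for j in order:
            # stop at the target, and never absorb a whole class into train
            if taken >= target or n_added == len(subjects) - 1:
                break
            train_subjects.append(subjects[j])
            taken += int(counts.iloc[j])
            n_added += 1
    in_train = manifest["subject_id"].isin(train_subjects)
    return (
        manifest[in_train].reset_index(drop=True),
        manifest[~in_train].reset_index(drop=True),
    )
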