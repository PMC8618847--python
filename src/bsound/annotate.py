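"""Bowel-sound interval annotations, frame labeling and dataset splitting.

Ground truth is a set of (start, end) intervals in seconds. The per-frame
binary label uses a two-condition rule: a 10-ms frame is a sound frame if
(a) annotated sound covers more than half of the frame, or (b) more than
half of the duration of some single annotated sound falls inside the frame.
Condition (b) matters for sounds shorter than a frame, which would otherwise
never be labeled positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationSet",
    "FrameLabels",
    "read_annotations",
    "write_annotations",
    "label_frames",
    "split_dataset",
    "kfold_indices",
]


class AnnotationFormatError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


def _merge_intervals(intervals) -> list[tuple[float, float]]:
    ivs = sorted((float(s), float(e)) for s, e in intervals)
    merged: list[list[float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass(frozen=True)
class AnnotationSet:
    """Sorted, overlap-merged sound intervals (seconds from recording start)."""

    intervals: tuple[tuple[float, float], ...]

    def __init__(self, intervals=()):
        for s, e in intervals:
            if not s < e:
                raise ValueError(f"interval start must precede end, got ({s}, {e})")
        object.__setattr__(self, "intervals", tuple(_merge_intervals(intervals)))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def shifted(self, offset_s: float) -> "AnnotationSet":
        """Annotations re-expressed relative to a later origin; intervals are
        clipped to [0, inf) and empty clips dropped."""
        out = []
        for s, e in self.intervals:
            s2, e2 = s - offset_s, e - offset_s
            if e2 > 0:
                out.append((max(s2, 0.0), e2))
        return AnnotationSet(out)


@dataclass(frozen=True)
class FrameLabels:
    """Binary per-frame labels aligned to a FrameTensor."""

    labels: np.ndarray = field(repr=False)
    frame_ms: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int8))

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def read_annotations(path) -> AnnotationSet:
    """Read a CSV with header columns ``start`` and ``end`` (seconds).

    Extra columns are ignored. Rows with end <= start raise a validation
    error naming the row; missing columns raise a format error.
    """
    df = pd.read_csv(path)
    missing = {"start", "end"} - set(df.columns)
    if missing:
        raise AnnotationFormatError(
            f"annotation file {path!r} lacks required column(s) {sorted(missing)}"
        )
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"annotation row {row}: end ({df['end'][row]}) must exceed "
            f"start ({df['start'][row]})"
        )
    return AnnotationSet(list(zip(df["start"].astype(float), df["end"].astype(float))))


def write_annotations(path, ann: AnnotationSet) -> None:
    pd.DataFrame(ann.intervals, columns=["start", "end"]).to_csv(path, index=False)


def label_frames(ann: AnnotationSet, n_frames: int, frame_ms: float = 10.0) -> FrameLabels:
    """Binary labels for frames [m*D, (m+1)*D), D = frame_ms/1000.

    Frame m is positive iff
      (a) the total annotated time inside the frame exceeds D/2 (strict), or
      (b) some single annotated sound has more than half of its own duration
          inside the frame (strict).
    """
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    D = frame_ms / 1000.0
    labels = np.zeros(n_frames, dtype=np.int8)
    if n_frames == 0 or len(ann) == 0:
        return FrameLabels(labels=labels, frame_ms=frame_ms)
    edges = D * np.arange(n_frames + 1)
    overlap_total = np.zeros(n_frames)
    for s, e in ann:
        lo = max(0, int(np.floor(s / D)))
        hi = min(n_frames - 1, int(np.ceil(e / D)))
        for m in range(lo, hi + 1):
            ov = min(e, edges[m + 1]) - max(s, edges[m])
            if ov <= 0:
                continue
            overlap_total[m] += ov
            if ov > 0.5 * (e - s):  # condition (b)
                labels[m] = 1
    labels[overlap_total > D / 2] = 1  # condition (a)
    return FrameLabels(labels=labels, frame_ms=frame_ms)


def split_dataset(items, test_frac: float = 0.15, seed: int = 0):
    """Random train/test partition of whole fragments.

    Splitting operates on fragments (never inside one), so near-identical
    adjacent frames cannot leak between sets. |test| = round(test_frac * n).
    Deterministic given ``seed``.
    """
    if not (0 < test_frac < 1):
        raise ValueError(f"test_frac must be in (0, 1), got {test_frac}")
    items = list(items)
    n = len(items)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 fragments to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_frac * n))
    test_idx = set(perm[:n_test].tolist())
    train = [items[i] for i in range(n) if i not in test_idx]
    test = [items[i] for i in range(n) if i in test_idx]
    return train, test


def kfold_indices(n_fragments: int, k: int = 5, seed: int = 0):
    """k (train_idx, val_idx) pairs; validation folds partition the fragments
    and differ in size by at most 1. Deterministic given ``seed``."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n_fragments < k:
        raise InsufficientDataError(f"need >= {k} fragments, got {n_fragments}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_fragments)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        val = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, val))
    return out
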