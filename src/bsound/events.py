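"""From per-frame decisions to discrete bowel-sound events.

A maximal run of consecutive positive frames is one event; adjacent positive
frames belong to the same sound. No minimum-duration filter and no
gap-bridging is applied by default — a single physiological sound split by
one negative frame is reported as two events, which matches how the frame
classifier output is quantified. An optional ``bridge_gap_frames`` is
provided for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detectors import FramePredictions

__all__ = ["SoundEvent", "merge_frames", "events_to_frames", "merge_adjacent"]


@dataclass(frozen=True)
class SoundEvent:
    """A detected bowel sound.

    start_s/end_s are frame-grid times; end_s - start_s = n_frames * frame
    width. mean_probability averages the classifier probability over the run.
    """

    start_s: float
    end_s: float
    n_frames: int
    mean_probability: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def merge_frames(pred: FramePredictions, frame_ms: float = 10.0,
                 offset_s: float = 0.0, bridge_gap_frames: int = 0) -> list[SoundEvent]:
    """Merge maximal runs of positive frames into events.

    Event start = offset_s + first_index * D and end = offset_s +
    (last_index + 1) * D with D = frame_ms / 1000. With
    ``bridge_gap_frames`` > 0, negative gaps up to that many frames between
    positive runs are absorbed into one event (off by default).
    """
    d = np.asarray(pred.decisions, dtype=np.int8).copy()
    if bridge_gap_frames > 0:
        d = _bridge(d, bridge_gap_frames)
    D = frame_ms / 1000.0
    events: list[SoundEvent] = []
    probs = pred.probabilities
    n = d.shape[0]
    i = 0
    while i < n:
        if d[i]:
            j = i
            while j + 1 < n and d[j + 1]:
                j += 1
            events.append(SoundEvent(
                start_s=offset_s + i * D,
                end_s=offset_s + (j + 1) * D,
                n_frames=j - i + 1,
                mean_probability=float(np.mean(probs[i : j + 1])),
            ))
            i = j + 1
        i += 1
    return events


def _bridge(d: np.ndarray, max_gap: int) -> np.ndarray:
    out = d.copy()
    pos = np.flatnonzero(d)
    for a, b in zip(pos[:-1], pos[1:]):
        if 1 < b - a <= max_gap + 1:
            out[a : b] = 1
    return out


def events_to_frames(events, n_frames: int, frame_ms: float = 10.0,
                     offset_s: float = 0.0) -> np.ndarray:
    """Binary decision vector whose merge is exactly ``events``.

    Events must lie within [offset_s, offset_s + n_frames * D]; this is the
    inverse of :func:`merge_frames` on its image (frame-grid-aligned,
    disjoint events).
    """
    D = frame_ms / 1000.0
    out = np.zeros(n_frames, dtype=np.int8)
    for ev in events:
        lo = (ev.start_s - offset_s) / D
        hi = (ev.end_s - offset_s) / D
        i0, i1 = int(round(lo)), int(round(hi))
        if i0 < 0 or i1 > n_frames:
            raise ValueError(f"event ({ev.start_s}, {ev.end_s}) lies outside "
                             f"the {n_frames}-frame grid")
        out[i0:i1] = 1
    return out


def merge_adjacent(events: list[SoundEvent], tol_s: float = 1e-9) -> list[SoundEvent]:
    """Post-hoc merge of touching events (e.g. across fragment boundaries).

    Off by default in the pipeline; provided because fragments are processed
    independently, so a sound spanning a boundary arrives as two touching
    events.
    """
    if not events:
        return []
    events = sorted(events, key=lambda e: e.start_s)
    merged = [events[0]]
    for ev in events[1:]:
        last = merged[-1]
        if ev.start_s - last.end_s <= tol_s:
            n = last.n_frames + ev.n_frames
            merged[-1] = SoundEvent(
                start_s=last.start_s, end_s=ev.end_s, n_frames=n,
                mean_probability=(last.mean_probability * last.n_frames
                                  + ev.mean_probability * ev.n_frames) / n)
        else:
            merged.append(ev)
    return merged
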