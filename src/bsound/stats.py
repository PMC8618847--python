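"""Clinical quantification of detected bowel sounds.

Beyond raw counts, the report borrows the vocabulary of heart-rate
variability analysis: the sequence of inter-event intervals (onset to onset,
the HRV convention the named statistics come from) is summarized by its
standard deviation and by RMSSD (root mean square of successive
differences), and its asymmetry by Porta's and Guzik's indices from the
Poincare-plot construction:

* Porta's index — the percentage of negative interval changes among all
  nonzero changes (points below the identity line).
* Guzik's index — the percentage of the total squared distance from the
  identity line contributed by positive changes (points above the line);
  the constant 1/sqrt(2) distance factor cancels.

Both sit near 50% for a symmetric, independent interval sequence; departures
indicate asymmetric accelerations/decelerations of the event rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .events import SoundEvent

__all__ = [
    "StatsReport",
    "intervals",
    "rmssd",
    "sd_intervals",
    "porta_index",
    "guzik_index",
    "compute_report",
]


@dataclass(frozen=True)
class StatsReport:
    """Quantitative summary of one recording's detected bowel sounds.

    Undefined statistics (too few events, or no nonzero interval changes)
    are reported as None rather than 0. Per-minute series cover whole
    minutes only; totals cover the full recording.
    """

    recording_length_s: float
    n_events: int
    events_per_min: float | None
    per_minute_counts: list[int]
    three_min_stats: list[dict]
    duration_histogram: dict[int, int]
    duration_percentages: dict[int, float]
    rmssd_s: float | None
    sd_intervals_s: float | None
    porta_index_pct: float | None
    guzik_index_pct: float | None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = [
            f"recording_length_s: {self.recording_length_s:.3f}",
            f"n_events: {self.n_events}",
            f"events_per_min: {_fmt(self.events_per_min)}",
            f"per_minute_counts: {self.per_minute_counts}",
        ]
        for w in self.three_min_stats:
            lines.append(
                f"window_{w['window_index']} (min {w['start_min']}-{w['end_min']}): "
                f"mean {w['mean']:.2f}, median {w['median']:.2f}, "
                f"q1 {w['q1']:.2f}, q3 {w['q3']:.2f}")
        hist = ", ".join(f"{ms} ms: {c}" for ms, c in sorted(self.duration_histogram.items()))
        pct = ", ".join(f"{ms} ms: {p:.1f}%" for ms, p in sorted(self.duration_percentages.items()))
        lines += [
            f"duration_histogram: {hist}",
            f"duration_percentages: {pct}",
            f"rmssd_s: {_fmt(self.rmssd_s)}",
            f"sd_intervals_s: {_fmt(self.sd_intervals_s)}",
            f"porta_index_pct: {_fmt(self.porta_index_pct)}",
            f"guzik_index_pct: {_fmt(self.guzik_index_pct)}",
        ]
        return "\n".join(lines)


def _fmt(v) -> str:
    return "undefined" if v is None else f"{v:.4f}"


def intervals(events: list[SoundEvent]) -> np.ndarray:
    """Onset-to-onset inter-event intervals, length n_events - 1."""
    starts = [e.start_s for e in events]
    if starts != sorted(starts):
        raise ValueError("events must be sorted by start time")
    return np.diff(np.asarray(starts, dtype=np.float64))


def rmssd(ivals: np.ndarray) -> float | None:
    """sqrt(mean((I_{i+1} - I_i)^2)); None with fewer than 2 intervals."""
    ivals = np.asarray(ivals, dtype=np.float64)
    if ivals.size < 2:
        return None
    d = np.diff(ivals)
    return float(np.sqrt(np.mean(d**2)))


def sd_intervals(ivals: np.ndarray) -> float | None:
    """Sample standard deviation (ddof=1) of the intervals; None if < 2."""
    ivals = np.asarray(ivals, dtype=np.float64)
    if ivals.size < 2:
        return None
    return float(np.std(ivals, ddof=1))


def porta_index(ivals: np.ndarray) -> float | None:
    """100 * #(negative changes) / #(nonzero changes); None if no nonzero
    change exists (fewer than 2 intervals, or a perfectly constant rhythm)."""
    ivals = np.asarray(ivals, dtype=np.float64)
    if ivals.size < 2:
        return None
    d = np.diff(ivals)
    nz = d[d != 0]
    if nz.size == 0:
        return None
    return float(100.0 * np.sum(nz < 0) / nz.size)


def guzik_index(ivals: np.ndarray) -> float | None:
    """100 * sum of squared positive changes / sum of squared nonzero changes.

    Squared Poincare-plot distances above the identity line over the total;
    the 1/sqrt(2) projection factor cancels. None when undefined.
    """
    ivals = np.asarray(ivals, dtype=np.float64)
    if ivals.size < 2:
        return None
    d = np.diff(ivals)
    denom = np.sum(d[d != 0] ** 2)
    if denom == 0:
        return None
    return float(100.0 * np.sum(d[d > 0] ** 2) / denom)


def compute_report(events: list[SoundEvent], recording_length_s: float,
                   bin_ms: float = 10.0, window_min: int = 3) -> StatsReport:
    """Assemble the full statistics report.

    Per-minute counts cover the floor(length/60) whole minutes (events are
    binned by onset); the overall rate is computed over those whole minutes
    so that an event-free trailing partial minute cannot change it (for
    recordings shorter than a minute the full duration is used). Three-minute
    windows are consecutive non-overlapping groups of whole minutes,
    summarized by mean/median/quartiles of their per-minute counts. The
    duration histogram bin b counts events with duration in
    ((b-1)*bin_ms, b*bin_ms]; percentages are shares of n_events.
    """
    if recording_length_s <= 0:
        raise ValueError("recording_length_s must be positive")
    events = sorted(events, key=lambda e: e.start_s)
    for ev in events:
        if ev.start_s < 0 or ev.end_s > recording_length_s + 1e-9:
            raise ValueError(f"event ({ev.start_s}, {ev.end_s}) outside recording")
    n_events = len(events)

    n_minutes = int(np.floor(recording_length_s / 60.0))
    starts = np.asarray([e.start_s for e in events])
    per_minute = [int(np.sum((starts >= 60.0 * m) & (starts < 60.0 * (m + 1))))
                  for m in range(n_minutes)]
    # rate over whole minutes keeps the report invariant to a short
    # event-free tail; see docstring
    if n_minutes >= 1:
        epm = n_events / n_minutes
    else:
        epm = n_events / (recording_length_s / 60.0)

    three_min = []
    counts = np.asarray(per_minute, dtype=np.float64)
    for w in range(n_minutes // window_min):
        seg = counts[w * window_min : (w + 1) * window_min]
        three_min.append({
            "window_index": w,
            "start_min": w * window_min,
            "end_min": (w + 1) * window_min,
            "mean": float(seg.mean()),
            "median": float(np.median(seg)),
            "q1": float(np.percentile(seg, 25)),
            "q3": float(np.percentile(seg, 75)),
        })

    hist: dict[int, int] = {}
    for ev in events:
        ms = ev.duration_s * 1000.0
        b = int(np.ceil(ms / bin_ms - 1e-9))  # ((b-1)*bin, b*bin]
        key = int(b * bin_ms)
        hist[key] = hist.get(key, 0) + 1
    pct = {k: 100.0 * v / n_events for k, v in hist.items()} if n_events else {}

    ivals = intervals(events) if n_events >= 2 else np.empty(0)
    return StatsReport(
        recording_length_s=float(recording_length_s),
        n_events=n_events,
        events_per_min=float(epm),
        per_minute_counts=per_minute,
        three_min_stats=three_min,
        duration_histogram=hist,
        duration_percentages=pct,
        rmssd_s=rmssd(ivals),
        sd_intervals_s=sd_intervals(ivals),
        porta_index_pct=porta_index(ivals),
        guzik_index_pct=guzik_index(ivals),
    )
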