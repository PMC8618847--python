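"""End-to-end wiring: audio -> fragments -> spectrograms -> frames -> model
-> events -> report.

These helpers assemble the arrays the classifiers train on and run the full
detection chain on a recording. Standardization statistics always come from
the training material (and are stored with the model); at detection time the
incoming recording is standardized with those stored statistics.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, audio_io, detectors, events as events_mod, spectro, stats

log = logging.getLogger("bsound")

__all__ = ["build_frame_dataset", "standardize_dataset", "run_detect_pipeline",
           "detections_to_csv"]

DEFAULT_FRAGMENT_S = 2.0


def build_frame_dataset(rec: audio_io.Recording, ann: annotate.AnnotationSet,
                        params: spectro.StftParams | None = None,
                        frame_ms: float = 10.0, cols_per_frame: int = 4,
                        fragment_s: float = DEFAULT_FRAGMENT_S):
    """Fragment a recording and derive per-fragment dB spectrograms and labels.

    Returns (fragments, spectrograms, labels) with labels aligned to the
    frame grid of each fragment (annotations are shifted to fragment-local
    time). Spectrograms are NOT yet standardized.
    """
    if params is None:
        params = spectro.default_params(sample_rate=rec.sample_rate)
    frags = audio_io.fragment(rec, fragment_s)
    specs, labels = [], []
    for fr in frags:
        sp = spectro.to_db_spectrogram(spectro.stft(fr, params), params,
                                       n_samples=fr.n_samples)
        n_frames = int(np.floor(fr.n_samples * 1000.0 / (frame_ms * rec.sample_rate) + 1e-9))
        local = ann.shifted(fr.offset_s)
        clipped = annotate.AnnotationSet(
            [(s, min(e, fr.duration_s)) for s, e in local if s < fr.duration_s])
        labels.append(annotate.label_frames(clipped, n_frames, frame_ms))
        specs.append(sp)
    return frags, specs, labels


def standardize_dataset(specs, labels, mean: float, std: float,
                        frame_ms: float = 10.0, cols_per_frame: int = 4):
    """Standardize spectrograms and stack them into model arrays.

    Returns (X, y): X of shape (n_fragments, n_frames, n_bins, cols), y of
    shape (n_fragments, n_frames).
    """
    xs, ys = [], []
    for sp, lab in zip(specs, labels):
        ft = spectro.frame_tensor(spectro.standardize(sp, mean, std),
                                  frame_ms, cols_per_frame)
        xs.append(ft.blocks)
        ys.append(lab.labels)
    return np.stack(xs), np.stack(ys)


def make_training_arrays(rec, ann, params=None, frame_ms=10.0, cols_per_frame=4,
                         fragment_s=DEFAULT_FRAGMENT_S):
    """Dataset arrays plus the global (mean, std) computed from all fragments."""
    _, specs, labels = build_frame_dataset(rec, ann, params, frame_ms,
                                           cols_per_frame, fragment_s)
    mean, std = spectro.compute_norm_stats(specs)
    x, y = standardize_dataset(specs, labels, mean, std, frame_ms, cols_per_frame)
    return x, y, (mean, std)


def run_detect_pipeline(rec_or_path, model=None, model_meta: dict | None = None,
                        baseline: detectors.BaselineConfig | None = None,
                        params: spectro.StftParams | None = None,
                        frame_ms: float = 10.0, cols_per_frame: int = 4,
                        fragment_s: float = DEFAULT_FRAGMENT_S,
                        threshold: float = 0.5,
                        merge_across_fragments: bool = False):
    """Run fragment -> spectrogram -> standardize -> frame -> predict ->
    merge -> report on one recording.

    Exactly one of ``model`` (with ``model_meta`` holding the training-time
    norm_mean/norm_std) or ``baseline`` must be given. With the baseline and
    no stored statistics, the recording's own global mean/std are used.
    Returns (events, StatsReport).
    """
    t0 = time.perf_counter()
    if (model is None) == (baseline is None):
        raise ValueError("provide exactly one of model= or baseline=")
    if isinstance(rec_or_path, (str, Path)):
        rec = audio_io.read_wav(rec_or_path)
    else:
        rec = rec_or_path
    if rec.sample_rate != audio_io.DEFAULT_SAMPLE_RATE:
        rec = audio_io.resample(rec, audio_io.DEFAULT_SAMPLE_RATE)
    if params is None:
        params = spectro.default_params(sample_rate=rec.sample_rate)

    frags = audio_io.fragment(rec, fragment_s)
    log.info("fragmented %.1f s into %d fragments", rec.duration_s, len(frags))
    specs = [spectro.to_db_spectrogram(spectro.stft(f, params), params,
                                       n_samples=f.n_samples) for f in frags]
    if model is not None:
        mean, std = model_meta["norm_mean"], model_meta["norm_std"]
        if mean is None or std is None:
            raise ValueError("model metadata lacks standardization statistics")
    else:
        mean, std = spectro.compute_norm_stats(specs)

    all_events: list[events_mod.SoundEvent] = []
    for fr, sp in zip(frags, specs):
        ft = spectro.frame_tensor(spectro.standardize(sp, mean, std),
                                  frame_ms, cols_per_frame)
        if model is not None:
            pred = detectors.predict(model, ft, threshold=threshold)
        else:
            pred = detectors.baseline_classify(ft, baseline)
        all_events.extend(events_mod.merge_frames(pred, frame_ms,
                                                  offset_s=fr.offset_s))
    if merge_across_fragments:
        all_events = events_mod.merge_adjacent(all_events)
    analysed_s = len(frags) * fragment_s
    report = stats.compute_report(all_events, analysed_s if frags else rec.duration_s)
    log.info("detected %d events in %.2f s of audio (%.1f ms elapsed)",
             len(all_events), rec.duration_s, 1e3 * (time.perf_counter() - t0))
    return all_events, report


def detections_to_csv(events, path) -> None:
    pd.DataFrame(
        [(e.start_s, e.end_s, e.n_frames, e.mean_probability) for e in events],
        columns=["start", "end", "n_frames", "mean_probability"],
    ).to_csv(path, index=False)


def read_detections(path) -> list:
    df = pd.read_csv(path)
    return [events_mod.SoundEvent(start_s=float(r.start), end_s=float(r.end),
                                  n_frames=int(r.n_frames),
                                  mean_probability=float(r.mean_probability))
            for r in df.itertuples()]
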