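"""Frame-level metrics, k-fold cross-validation and hyperparameter sweeps.

Metrics follow the frame-classification convention: accuracy, precision,
sensitivity (true-positive rate on sound frames) and specificity
(true-negative rate on noise frames), all in percent. Ratios with a zero
denominator are reported as None rather than 0, so degenerate folds cannot
silently corrupt a sweep table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import FrameLabels, kfold_indices

__all__ = ["EvalResult", "confusion", "cross_validate", "sweep", "SWEEP_AXES"]


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float | None:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    def as_row(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "ACC": self.accuracy, "Prec.": self.precision,
                "Sensitivity": self.sensitivity, "Specificity": self.specificity}


def confusion(pred, truth) -> EvalResult:
    """Tally the four outcome cells of binary frame decisions vs truth."""
    p = np.asarray(pred.labels if isinstance(pred, FrameLabels) else pred).astype(bool).ravel()
    t = np.asarray(truth.labels if isinstance(truth, FrameLabels) else truth).astype(bool).ravel()
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return EvalResult(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def cross_validate(dataset, model_spec, train_cfg, k: int = 5, seed: int = 0):
    """k-fold cross-validation over whole fragments.

    ``dataset`` is (X, y) with X (n_fragments, T, bins, cols). Each fold
    trains on the other k-1 folds, tracks every epoch on the held-out fold,
    and reports the metrics of the best epoch (by validation accuracy, whose
    weights the training loop retains). Returns (fold_results, mean_row).
    """
    from . import detectors

    x, y = dataset
    pairs = kfold_indices(x.shape[0], k=k, seed=seed)
    fold_results: list[EvalResult] = []
    for i, (tr, va) in enumerate(pairs):
        model = detectors.build_model(model_spec, seed=seed + i)
        detectors.train(model, (x[tr], y[tr]), (x[va], y[va]), train_cfg)
        probs = model.predict_proba(x[va])
        res = confusion((probs > train_cfg.threshold).reshape(-1), y[va].reshape(-1))
        fold_results.append(res)
    mean_row = {
        m: float(np.mean([getattr(r, m) for r in fold_results
                          if getattr(r, m) is not None]))
        for m in ("accuracy", "precision", "sensitivity", "specificity")
        if any(getattr(r, m) is not None for r in fold_results)
    }
    return fold_results, mean_row


SWEEP_AXES = ("max_freq", "fft", "window", "n_frames_context", "sigma")


def sweep(axis: str, values, rec, ann, model_spec, train_cfg,
          k: int = 5, seed: int = 0, frame_ms: float = 10.0,
          cols_per_frame: int = 4, fragment_s: float = 2.0) -> pd.DataFrame:
    """Cross-validated metric table along one hyperparameter axis.

    One row per value; only the swept parameter changes between rows. For
    the ``fft`` axis the hop is recomputed as floor(fft/4) and for the
    spectrogram axes the model input height follows the retained bin count.
    Columns use the conventional order: value, ACC, Prec., Sensitivity,
    Specificity (plus the summed confusion counts).
    """
    from dataclasses import replace

    from . import pipeline, spectro

    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")
    rows = []
    for v in values:
        params = spectro.default_params(sample_rate=rec.sample_rate)
        spec_i, cfg_i = model_spec, train_cfg
        if axis == "max_freq":
            params = spectro.default_params(sample_rate=rec.sample_rate, max_freq=float(v))
        elif axis == "fft":
            params = spectro.default_params(fft=int(v), sample_rate=rec.sample_rate)
        elif axis == "window":
            params = spectro.default_params(window=str(v), sample_rate=rec.sample_rate)
        elif axis == "n_frames_context":
            spec_i = replace(model_spec, context=int(v))
        elif axis == "sigma":
            cfg_i = replace(train_cfg, augmentation_sigma=float(v))
        n_bins = int(np.floor(params.max_freq / params.bin_hz + 1e-9))
        spec_i = replace(spec_i, n_bins=n_bins)
        x, y, _ = pipeline.make_training_arrays(rec, ann, params, frame_ms,
                                                cols_per_frame, fragment_s)
        folds, mean_row = cross_validate((x, y), spec_i, cfg_i, k=k, seed=seed)
        row = {"value": v,
               "ACC": mean_row.get("accuracy"),
               "Prec.": mean_row.get("precision"),
               "Sensitivity": mean_row.get("sensitivity"),
               "Specificity": mean_row.get("specificity"),
               "tp": sum(r.tp for r in folds), "fp": sum(r.fp for r in folds),
               "tn": sum(r.tn for r in folds), "fn": sum(r.fn for r in folds)}
        rows.append(row)
    return pd.DataFrame(rows)
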