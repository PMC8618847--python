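"""Decibel spectrograms and their regrouping into classification frames.

The short-time Fourier transform used here is the literal windowed DFT

    X[k, m] = sum_{n=0}^{L-1} w_n * x[m*hop + n] * exp(-2*pi*i*k*n/L)

with no centering and no zero-padding: column m covers samples
[m*hop, m*hop + L) and the column count is floor((n_samples - L)/hop) + 1.
Amplitudes are mapped to decibels (20*log10, reference 1.0, clamped at a
floor), the frequency axis is cropped to the band where bowel sounds live
(60-1500 Hz in practice; the crop keeps 0 < f <= max_freq, excluding DC),
and the columns are regrouped into 10-ms frames of ``cols_per_frame``
columns each — the unit the frame classifiers consume.

At the default parameters (44.1 kHz, L=441, hop=110, max_freq=1500) a 2-s
fragment maps to exactly 200 frames of 15 frequency bins x 4 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .audio_io import Recording

__all__ = [
    "WindowSpec",
    "StftParams",
    "Spectrogram",
    "FrameTensor",
    "window_weights",
    "stft",
    "to_db_spectrogram",
    "compute_norm_stats",
    "standardize",
    "frame_tensor",
    "default_params",
]


class ConfigError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSpec:
    """Taper function applied to each analysis window.

    kind : 'hann' or 'hamming'
    size_L : window length in samples.
    """

    kind: str = "hann"
    size_L: int = 441

    def __post_init__(self) -> None:
        if self.kind not in ("hann", "hamming"):
            raise ConfigError(f"unknown window kind {self.kind!r}")
        if self.size_L < 2:
            raise ConfigError(f"window size_L must be >= 2, got {self.size_L}")


@dataclass(frozen=True)
class StftParams:
    window: WindowSpec = field(default_factory=WindowSpec)
    hop: int = 110
    sample_rate: int = 44_100
    max_freq: float = 1500.0
    db_floor: float = -100.0

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.window.size_L):
            raise ConfigError(f"hop must be in (0, L], got {self.hop}")
        if not (0 < self.max_freq <= self.sample_rate / 2):
            raise ConfigError(
                f"max_freq must be in (0, sample_rate/2], got {self.max_freq}"
            )

    @property
    def bin_hz(self) -> float:
        """Frequency spacing of the DFT bins: sample_rate / L."""
        return self.sample_rate / self.window.size_L


def default_params(fft: int = 441, window: str = "hann", sample_rate: int = 44_100,
                   max_freq: float = 1500.0, hop: int | None = None,
                   db_floor: float = -100.0) -> StftParams:
    """Standard analysis parameters; hop defaults to floor(fft/4) (25%)."""
    if hop is None:
        hop = fft // 4
    return StftParams(window=WindowSpec(kind=window, size_L=fft), hop=hop,
                      sample_rate=sample_rate, max_freq=max_freq, db_floor=db_floor)


@dataclass(frozen=True)
class Spectrogram:
    """Time x frequency matrix of dB amplitudes for one fragment.

    values : array [n_cols, n_bins]
    freq_axis : Hz per retained bin (strictly increasing, <= max_freq)
    time_axis : window-start time in seconds per column
    n_samples : length of the source fragment in samples
    """

    values: np.ndarray = field(repr=False)
    freq_axis: np.ndarray = field(repr=False)
    time_axis: np.ndarray = field(repr=False)
    params: StftParams
    n_samples: int
    standardized: bool = False

    @property
    def n_cols(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FrameTensor:
    """Per-frame regrouping of a spectrogram: [n_frames, n_bins, cols_per_frame]."""

    blocks: np.ndarray = field(repr=False)
    frame_ms: float
    standardized: bool = False

    @property
    def n_frames(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_bins(self) -> int:
        return self.blocks.shape[1]

    @property
    def cols_per_frame(self) -> int:
        return self.blocks.shape[2]


def window_weights(spec: WindowSpec) -> np.ndarray:
    """Window weights w_0..w_N with N = size_L - 1.

    Hann:    w(n) = 0.5 * (1 - cos(2*pi*n/N))
    Hamming: w(n) = 0.54 - 0.46 * cos(2*pi*n/N)

    Both are symmetric about N/2; the Hann endpoints are exactly zero.
    """
    N = spec.size_L - 1
    n = np.arange(spec.size_L, dtype=np.float64)
    c = np.cos(2.0 * np.pi * n / N)
    if spec.kind == "hann":
        return 0.5 * (1.0 - c)
    return 0.54 - 0.46 * c


def stft(rec: Recording, params: StftParams) -> np.ndarray:
    """Complex STFT coefficients, shape [n_cols, L].

    Column m is the L-point DFT of w * x[m*hop : m*hop + L]. The signal must
    be at least one window long; nothing is padded or centered.
    """
    L = params.window.size_L
    hop = params.hop
    x = rec.samples
    if x.shape[0] < L:
        raise EmptyInputError(
            f"signal has {x.shape[0]} samples, shorter than the {L}-sample window"
        )
    M = (x.shape[0] - L) // hop + 1
    idx = np.arange(L)[None, :] + hop * np.arange(M)[:, None]
    frames = x[idx] * window_weights(params.window)[None, :]
    return np.fft.fft(frames, axis=1)


def to_db_spectrogram(coeffs: np.ndarray, params: StftParams,
                      n_samples: int | None = None) -> Spectrogram:
    """Map STFT coefficients to a dB spectrogram cropped to (0, max_freq].

    value = 20*log10(max(|X|, eps)) with eps = 10**(db_floor/20). Bin k of
    the DFT sits at f = k * sample_rate / L; DC (k=0) is excluded from the
    crop since it carries sensor offset rather than sound. At the defaults
    this keeps 15 bins at 100, 200, ..., 1500 Hz.
    """
    L = params.window.size_L
    k_max = int(np.floor(params.max_freq / params.bin_hz + 1e-9))
    k = np.arange(1, k_max + 1)
    mag = np.abs(coeffs[:, 1 : k_max + 1])
    eps = 10.0 ** (params.db_floor / 20.0)
    vals = 20.0 * np.log10(np.maximum(mag, eps))
    M = coeffs.shape[0]
    if n_samples is None:
        n_samples = (M - 1) * params.hop + L
    return Spectrogram(
        values=vals,
        freq_axis=k * params.bin_hz,
        time_axis=params.hop * np.arange(M) / params.sample_rate,
        params=params,
        n_samples=n_samples,
    )


def compute_norm_stats(spectrograms) -> tuple[float, float]:
    """Global scalar mean and standard deviation over all cells of all
    provided spectrograms (the standardization statistics of the pipeline)."""
    specs = list(spectrograms)
    if not specs:
        raise EmptyInputError("need at least one spectrogram to compute stats")
    total = sum(s.values.size for s in specs)
    if total < 2:
        raise EmptyInputError("need at least 2 cells to compute a std")
    mean = sum(s.values.sum() for s in specs) / total
    ss = sum(((s.values - mean) ** 2).sum() for s in specs)
    return float(mean), float(np.sqrt(ss / total))


def standardize(spec: Spectrogram, mean: float, std: float) -> Spectrogram:
    """(value - mean) / std, flagging the result as standardized."""
    if std <= 0:
        raise ValueError(f"std must be positive, got {std}")
    return replace(spec, values=(spec.values - mean) / std, standardized=True)


def frame_tensor(spec: Spectrogram, frame_ms: float = 10.0,
                 cols_per_frame: int = 4) -> FrameTensor:
    """Regroup spectrogram columns into per-frame blocks.

    Frame m covers samples [m*F, (m+1)*F) with F = frame_ms * fs / 1000; its
    block is the ``cols_per_frame`` consecutive columns starting at column
    floor(m*F / hop), zero-padded on the right where the spectrogram ends.
    n_frames = floor(fragment_samples / F). Values are never altered, only
    sliced; blocks are indexed [bin, column].
    """
    if cols_per_frame < 1:
        raise ConfigError(f"cols_per_frame must be >= 1, got {cols_per_frame}")
    F = frame_ms * spec.params.sample_rate / 1000.0
    n_frames = int(np.floor(spec.n_samples / F + 1e-9))
    starts = np.floor(np.arange(n_frames) * F / spec.params.hop + 1e-9).astype(int)
    pad_to = (int(starts[-1]) + cols_per_frame) if n_frames else 0
    padded = np.zeros((max(pad_to, spec.n_cols), spec.n_bins), dtype=spec.values.dtype)
    padded[: spec.n_cols] = spec.values
    blocks = np.empty((n_frames, spec.n_bins, cols_per_frame), dtype=spec.values.dtype)
    for m, c in enumerate(starts):
        blocks[m] = padded[c : c + cols_per_frame].T
    return FrameTensor(blocks=blocks, frame_ms=frame_ms, standardized=spec.standardized)
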