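"""WAV ingest, normalization, resampling and fragmentation.

All downstream processing assumes a 44.1 kHz mono signal with amplitudes in
[-1, 1]; this module is the single place where arbitrary PCM WAV input is
coerced into that form. Recordings are cut into fixed-length fragments
(2 s by default), the unit on which spectrograms are built and models run.
"""

from __future__ import annotations

import struct
import wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["Recording", "read_wav", "write_wav", "resample", "fragment"]

DEFAULT_SAMPLE_RATE = 44_100


class AudioFormatError(ValueError):
    """Raised when a file is not a readable PCM/float WAV."""


class EmptyInputError(ValueError):
    """Raised when audio contains no samples."""


@dataclass(frozen=True)
class Recording:
    """A mono audio signal with unit-normalized amplitudes.

    Attributes
    ----------
    samples : np.ndarray
        1-D float64 array of amplitudes in [-1, 1].
    sample_rate : int
        Sampling rate in Hz.
    offset_s : float
        Start time of this recording relative to its source (0 for a full
        recording; the fragment start for fragments).
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: int
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1:
            raise ValueError("Recording samples must be one-dimensional (mono)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


# int PCM is scaled by the full-scale value of the container dtype scipy
# returns (24-bit arrives upscaled into int32, so 2**31 is correct for it).
_INT_SCALE = {np.dtype(np.int16): 2.0**15, np.dtype(np.int32): 2.0**31,
              np.dtype(np.uint8): 2.0**7}


def read_wav(path: str | Path) -> Recording:
    """Read a PCM or IEEE-float WAV file as a normalized mono Recording.

    Integer PCM is scaled to [-1, 1] by the full-scale value of its bit
    depth; multi-channel audio is averaged down to mono.
    """
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise EmptyInputError(f"WAV file {path!r} contains no audio samples")
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        x = (data.astype(np.float64) - 128.0) / _INT_SCALE[data.dtype]
    elif data.dtype in _INT_SCALE:
        x = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")
    if x.ndim == 2:
        x = x.mean(axis=1)
    return Recording(samples=x, sample_rate=int(rate))


def write_wav(path: str | Path, rec: Recording, subtype: str = "float32") -> None:
    """Write a Recording to a WAV file.

    ``subtype`` is one of ``float32``, ``int16``, ``int24``, ``int32``.
    Float output round-trips losslessly through :func:`read_wav`; integer
    output is quantized to within one LSB of the chosen depth.
    """
    x = np.clip(rec.samples, -1.0, 1.0)
    if subtype == "float32":
        wavfile.write(str(path), rec.sample_rate, x.astype(np.float32))
    elif subtype == "int16":
        q = np.clip(np.round(x * 2**15), -(2**15), 2**15 - 1).astype(np.int16)
        wavfile.write(str(path), rec.sample_rate, q)
    elif subtype == "int32":
        q = np.clip(np.round(x * 2**31), -(2**31), 2**31 - 1).astype(np.int64)
        wavfile.write(str(path), rec.sample_rate, q.astype(np.int32))
    elif subtype == "int24":
        _write_wav_24bit(path, rec.sample_rate, x)
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}")


def _write_wav_24bit(path: str | Path, rate: int, x: np.ndarray) -> None:
    # stdlib wave handles sampwidth=3 frames; scipy cannot write 24-bit
    q = np.clip(np.round(x * 2**23), -(2**23), 2**23 - 1).astype(np.int64)
    as32 = (q.astype(np.int32) << 8).astype("<i4")  # 24 data bits in the top bytes
    frames = as32.tobytes()
    # drop every 4th byte (the low pad byte) to get packed 24-bit LE
    packed = np.frombuffer(frames, dtype=np.uint8).reshape(-1, 4)[:, 1:].tobytes()
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(3)
        w.setframerate(rate)
        w.writeframes(packed)


def resample(rec: Recording, target_rate: int) -> Recording:
    """Resample to ``target_rate`` Hz (polyphase filtering); no-op when the
    rates already match. Duration is preserved to within one sample period."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.sample_rate:
        return rec
    from math import gcd

    g = gcd(target_rate, rec.sample_rate)
    up, down = target_rate // g, rec.sample_rate // g
    y = resample_poly(rec.samples, up, down)
    return Recording(samples=y, sample_rate=target_rate, offset_s=rec.offset_s)


def fragment(rec: Recording, fragment_s: float = 2.0) -> list[Recording]:
    """Cut a recording into consecutive non-overlapping fragments of exactly
    ``fragment_s`` seconds.

    The trailing remainder shorter than one fragment is discarded. Each
    fragment carries its source offset in ``offset_s``. A recording shorter
    than ``fragment_s`` yields an empty list.
    """
    if fragment_s <= 0:
        raise ValueError(f"fragment_s must be positive, got {fragment_s}")
    n_frag_samples = int(round(fragment_s * rec.sample_rate))
    n = rec.n_samples // n_frag_samples
    out = []
    for i in range(n):
        lo = i * n_frag_samples
        out.append(
            Recording(
                samples=rec.samples[lo : lo + n_frag_samples],
                sample_rate=rec.sample_rate,
                offset_s=rec.offset_s + lo / rec.sample_rate,
            )
        )
    return out
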