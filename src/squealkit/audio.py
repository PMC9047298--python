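"""WAV reading/writing, mono conversion and peak normalization.

A squeal clip is analyzed as a unitless waveform in [-1, 1]: absolute
sound pressure is unknown in a free-roaming recording environment, so
every clip is scaled so that its absolute peak is exactly 1.  Stereo
recordings are reduced to mono by keeping the left channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from squealkit.errors import BoundsError, DegenerateSignalError, FormatError

__all__ = ["AudioClip", "load_wav", "write_wav", "extract_segment", "peak_normalize"]


@dataclass(frozen=True)
class AudioClip:
    """A mono, peak-normalized waveform with its sample rate.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes, unitless, in [-1, 1] after normalization.
    sample_rate : int
        Sampling frequency in Hz, positive.
    id : str
        Opaque label (file stem, cohort clip id, ...).
    """

    samples: np.ndarray
    sample_rate: int
    id: str = field(default="clip")

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a nonempty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Clip duration in seconds (N / fs)."""
        return self.samples.size / self.sample_rate


def peak_normalize(samples: np.ndarray) -> np.ndarray:
    """Scale so the absolute peak is 1. Idempotent; rejects all-zero input."""
    samples = np.asarray(samples, dtype=np.float64)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak == 0.0:
        raise DegenerateSignalError("all-zero signal cannot be normalized")
    return samples / peak


def _pcm_to_float(data: np.ndarray) -> np.ndarray:
    """Integer PCM -> float by division by the dtype's max magnitude."""
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    info = np.iinfo(data.dtype)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64) / float(max(abs(info.min), info.max))


def load_wav(path: str | Path, channel_policy: str = "left") -> AudioClip:
    """Read a PCM WAV file as a mono, peak-normalized :class:`AudioClip`.

    Stereo files are converted to mono by keeping the left channel and
    discarding the right one.

    Parameters
    ----------
    path : path-like
        RIFF/WAV file, 1 or 2 channels, integer or float PCM.
    channel_policy : {"left"}
        Which channel survives mono conversion; only "left" is defined.

    Raises
    ------
    FormatError
        If the file is not a readable WAV.
    DegenerateSignalError
        If the selected channel is all zeros.
    """
    if channel_policy != "left":
        raise ValueError(f"unknown channel policy: {channel_policy!r}")
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[:, 0]
    elif data.ndim != 1:
        raise FormatError(f"unsupported channel layout in {path}")
    samples = peak_normalize(_pcm_to_float(data))
    return AudioClip(samples=samples, sample_rate=int(rate), id=path.stem)


def write_wav(path: str | Path, clip: AudioClip, *, dtype: str = "int16") -> None:
    """Write a clip as PCM WAV (16-bit by default, or float32)."""
    path = Path(path)
    if dtype == "int16":
        scaled = np.clip(clip.samples, -1.0, 1.0) * np.iinfo(np.int16).max
        wavfile.write(path, clip.sample_rate, scaled.astype(np.int16))
    elif dtype == "float32":
        wavfile.write(path, clip.sample_rate, clip.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported WAV dtype: {dtype!r}")


def extract_segment(clip: AudioClip, start_s: float, end_s: float) -> AudioClip:
    """Carve the half-open time interval [start_s, end_s) out of a clip.

    Sample indices are floor(t * fs); the result is re-normalized to
    peak 1 so every extracted squeal is self-contained.

    Raises
    ------
    BoundsError
        If bounds are inverted or outside [0, duration].
    """
    if not (0.0 <= start_s < end_s <= clip.duration_s + 1e-12):
        raise BoundsError(
            f"segment [{start_s}, {end_s}) outside clip of {clip.duration_s:.6f} s"
        )
    i0 = int(np.floor(start_s * clip.sample_rate))
    i1 = int(np.floor(end_s * clip.sample_rate))
    i1 = min(i1, clip.n_samples)
    if i1 <= i0:
        raise BoundsError("segment contains no samples")
    return replace(clip, samples=peak_normalize(clip.samples[i0:i1]))
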