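"""Frequency-domain primitives: spectra, quantiles, flatness, flux.

All spectra are one-sided (0 ... Nyquist) with FFT length equal to the
window length (no zero padding).  Energy spectra carry the conventional
one-sided doubling of interior bins so that the total spectral energy
equals N * sum(x^2) (Parseval).  The DC bin is included in every
spectral sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from squealkit.errors import DegenerateSignalError, InsufficientSamplesError

__all__ = [
    "Spectrum",
    "energy_spectrum",
    "magnitude_spectrum",
    "spectral_quantile",
    "peak_frequency",
    "spectral_flatness",
    "spectral_flux",
]


@dataclass(frozen=True)
class Spectrum:
    """One-sided spectrum: frequencies in Hz and nonnegative values per bin."""

    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "values", values)
        if freqs.shape != values.shape or freqs.ndim != 1:
            raise ValueError("freqs and values must be matching 1-D arrays")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("spectral values must be nonnegative")

    @property
    def total(self) -> float:
        return float(np.sum(self.values))


def _one_sided_scale(n: int) -> np.ndarray:
    """Doubling factors for interior bins of a length-n one-sided spectrum."""
    n_bins = n // 2 + 1
    scale = np.full(n_bins, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:  # Nyquist bin is unpaired
        scale[-1] = 1.0
    return scale


def energy_spectrum(segment: np.ndarray, sample_rate: int) -> Spectrum:
    """One-sided energy spectrum |DFT|^2 of a (possibly tapered) segment.

    Interior bins are doubled so that ``sum(values) == N * sum(x**2)``
    up to rounding. Bin k sits at frequency k * fs / N.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size < 2:
        raise InsufficientSamplesError("spectrum needs at least 2 samples")
    spec = np.fft.rfft(segment)
    values = (spec.real**2 + spec.imag**2) * _one_sided_scale(segment.size)
    freqs = np.fft.rfftfreq(segment.size, d=1.0 / sample_rate)
    return Spectrum(freqs=freqs, values=values)


def magnitude_spectrum(segment: np.ndarray, sample_rate: int) -> Spectrum:
    """One-sided magnitude spectrum |DFT| of a segment (no doubling)."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size < 2:
        raise InsufficientSamplesError("spectrum needs at least 2 samples")
    values = np.abs(np.fft.rfft(segment))
    freqs = np.fft.rfftfreq(segment.size, d=1.0 / sample_rate)
    return Spectrum(freqs=freqs, values=values)


def spectral_quantile(spec: Spectrum, q: float) -> float:
    """Frequency splitting the spectrum's energy into q : (1-q) parts.

    Returns ``freqs[k*]`` for the smallest bin k* whose cumulative energy
    (from DC upward) reaches ``q * total``; no interpolation between bins.

    Raises
    ------
    DegenerateSignalError
        If the spectrum carries no energy.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    total = spec.total
    if total <= 0.0:
        raise DegenerateSignalError("zero-energy spectrum has no quantile")
    cum = np.cumsum(spec.values)
    k = int(np.searchsorted(cum, q * total, side="left"))
    return float(spec.freqs[min(k, spec.freqs.size - 1)])


def peak_frequency(spec: Spectrum) -> float:
    """Frequency of the maximum-energy bin; ties go to the lowest frequency."""
    if spec.total <= 0.0:
        raise DegenerateSignalError("zero-energy spectrum has no peak")
    return float(spec.freqs[int(np.argmax(spec.values))])


def spectral_flatness(spec: Spectrum) -> float:
    """Geometric over arithmetic mean of spectral energy, in [0, 1].

    1 for a perfectly flat (white-noise-like) spectrum, 0 whenever any
    bin is exactly zero (no flooring is applied).
    """
    values = spec.values
    amean = float(np.mean(values))
    if amean <= 0.0:
        raise DegenerateSignalError("all-zero spectrum has no flatness")
    if np.any(values == 0.0):
        return 0.0
    if np.all(values == values[0]):  # constant spectrum is flat by definition
        return 1.0
    return float(np.exp(np.mean(np.log(values / amean))))


def spectral_flux(frames: list[Spectrum] | tuple[Spectrum, ...], reduce: str = "mean") -> float:
    """Aggregate squared difference between neighboring normalized spectra.

    Each frame's values are first scaled to sum to 100 ("% magnitude"),
    so flux is invariant to per-frame loudness.  For every neighboring
    pair the squared bin-wise differences are summed over frequency;
    the pair sums are then averaged over time (``reduce="mean"``, the
    default) or summed (``reduce="sum"``).

    Raises
    ------
    InsufficientSamplesError
        If fewer than two frames are given.
    DegenerateSignalError
        If any frame has zero total (cannot be normalized to percent).
    """
    if len(frames) < 2:
        raise InsufficientSamplesError("flux needs at least two frames")
    if reduce not in ("mean", "sum"):
        raise ValueError(f"unknown flux reduction: {reduce!r}")
    grid = frames[0].freqs
    normed = []
    for frame in frames:
        if frame.freqs.shape != grid.shape or not np.array_equal(frame.freqs, grid):
            raise ValueError("all frames must share one frequency grid")
        total = frame.total
        if total <= 0.0:
            raise DegenerateSignalError("zero-total frame cannot be normalized")
        normed.append(frame.values * (100.0 / total))
    arr = np.stack(normed)
    pair_sums = np.sum(np.diff(arr, axis=0) ** 2, axis=1)
    return float(np.mean(pair_sums) if reduce == "mean" else np.sum(pair_sums))
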