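"""The three time-windowing schemes used by the parameter set.

total
    one rectangular window over the whole squeal (maximal frequency
    resolution; used by PF, Q50, SF_Q50, RMSI, Dur).
partial
    eleven evenly spaced, contiguous Hamming windows tiling the squeal
    (used by the windowed Q50 family); "inner windows" are indices 2-10
    in 1-based counting.
consecutive
    fixed-length overlapping frames, by default 1024 samples with 50%
    overlap and a Hamming taper (used by Q50W, Q25, SF and Flux).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows as _sigwin

from squealkit.audio import AudioClip
from squealkit.errors import InsufficientSamplesError

__all__ = ["WindowPlan", "partial_windows", "consecutive_windows"]


@dataclass(frozen=True)
class WindowPlan:
    """Windowing configuration shared by all windowed parameters.

    Parameters
    ----------
    n_partial : int
        Number of evenly spaced partial windows (>= 3 so that inner
        windows exist). Default 11.
    frame_len : int
        Consecutive-frame length in samples. Default 1024.
    overlap_frac : float
        Fractional overlap of consecutive frames, in [0, 1). Default 0.5.
    taper : {"hamming", "rectangular"}
        Taper applied to partial and consecutive windows.
    """

    n_partial: int = 11
    frame_len: int = 1024
    overlap_frac: float = 0.5
    taper: str = "hamming"

    def __post_init__(self) -> None:
        if self.n_partial < 3:
            raise ValueError("n_partial must be >= 3")
        if self.frame_len < 2:
            raise ValueError("frame_len must be >= 2")
        if not (0.0 <= self.overlap_frac < 1.0):
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.taper not in ("hamming", "rectangular"):
            raise ValueError(f"unknown taper: {self.taper!r}")

    @property
    def hop(self) -> int:
        """Consecutive-frame hop in samples: frame_len * (1 - overlap)."""
        hop = int(round(self.frame_len * (1.0 - self.overlap_frac)))
        return max(hop, 1)


def _taper(plan: WindowPlan, length: int) -> np.ndarray:
    if plan.taper == "hamming":
        return _sigwin.hamming(length, sym=True)
    return np.ones(length)


def partial_windows(clip: AudioClip, plan: WindowPlan = WindowPlan()) -> list[np.ndarray]:
    """Split a clip into ``n_partial`` contiguous equal-length tapered segments.

    Segment length is L = floor(N / n_partial); segments start at
    0, L, 2L, ...; the trailing N - n_partial*L samples are unused.
    Each segment is multiplied by the plan's taper.

    Raises
    ------
    InsufficientSamplesError
        If the clip has fewer than ``2 * n_partial`` samples
        (each segment needs at least 2 samples for a spectrum).
    """
    n = clip.n_samples
    seg_len = n // plan.n_partial
    if seg_len < 2:
        raise InsufficientSamplesError(
            f"clip of {n} samples cannot be tiled into {plan.n_partial} windows"
        )
    taper = _taper(plan, seg_len)
    return [
        clip.samples[i * seg_len : (i + 1) * seg_len] * taper
        for i in range(plan.n_partial)
    ]


def consecutive_windows(clip: AudioClip, plan: WindowPlan = WindowPlan()) -> list[np.ndarray]:
    """Slice a clip into overlapping fixed-length tapered frames.

    Frames start at multiples of the hop; every frame lies fully inside
    the signal, so the frame count is floor((N - frame_len)/hop) + 1.

    Raises
    ------
    InsufficientSamplesError
        If the clip is shorter than one frame.
    """
    n = clip.n_samples
    if n < plan.frame_len:
        raise InsufficientSamplesError(
            f"clip of {n} samples shorter than one {plan.frame_len}-sample frame"
        )
    hop = plan.hop
    n_frames = (n - plan.frame_len) // hop + 1
    taper = _taper(plan, plan.frame_len)
    return [
        clip.samples[i * hop : i * hop + plan.frame_len] * taper
        for i in range(n_frames)
    ]
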