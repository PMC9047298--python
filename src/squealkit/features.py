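"""Per-squeal parameter extraction: the 14 aperiodic parameters.

Parameters by windowing scheme:

total (whole squeal, rectangular window)
    PF    peak frequency of the energy spectrum [Hz]
    Q50   50% spectral energy quantile [Hz]
    SF_Q50  spectral flatness of the total spectrum divided by Q50 [1/Hz]
    Dur   duration [s]
    RMSI  root mean square of the peak-normalized waveform
    HNR   harmonics-to-noise ratio [dB] (autocorrelation harmonicity)

partial (eleven contiguous Hamming windows)
    Q50_2, Q50_10   Q50 of the 2nd / 2nd-to-last window [Hz]
    Q50_min         lowest Q50 of the nine inner windows (2-10) [Hz]
    Q50_n           1-based index of the inner window with the highest Q50

consecutive (1024-sample frames, 50% overlap, Hamming)
    Q50W  quantile of the bin-wise averaged energy spectrum [Hz]
    Q25   per-frame 25% quantile, averaged [Hz]
    SF    per-frame spectral flatness, averaged
    Flux  aggregate squared difference of %-normalized magnitude spectra

CPP (cepstral peak prominence, dB) is available as an optional extra but
stays off the statistical path, as it presumes a detectable fundamental.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from squealkit.audio import AudioClip
from squealkit.errors import DegenerateSignalError, InsufficientSamplesError
from squealkit.spectral import (
    Spectrum,
    energy_spectrum,
    magnitude_spectrum,
    peak_frequency,
    spectral_flatness,
    spectral_flux,
    spectral_quantile,
)
from squealkit.windows import WindowPlan, consecutive_windows, partial_windows

__all__ = [
    "PARAMETER_NAMES",
    "duration",
    "rmsi",
    "q50_partials",
    "q50w",
    "q25_mean",
    "sf_mean",
    "sf_q50",
    "hnr",
    "cpp",
    "compute_parameter_vector",
    "SquealFeatureExtractor",
]

#: The 14 aperiodic parameters, in canonical table order.
PARAMETER_NAMES = (
    "PF",
    "Q50",
    "Q50_2",
    "Q50_10",
    "Q50_min",
    "Q50W",
    "Q25",
    "Dur",
    "Q50_n",
    "SF",
    "SF_Q50",
    "Flux",
    "RMSI",
    "HNR",
)

INNER_WINDOWS = range(2, 11)  # 1-based indices of the nine inner partial windows


def duration(clip: AudioClip) -> float:
    """Squeal duration in seconds."""
    return clip.duration_s


def rmsi(clip: AudioClip) -> float:
    """Root mean square of the peak-normalized waveform; in (0, 1]."""
    return float(np.sqrt(np.mean(clip.samples**2)))


def q50_partials(clip: AudioClip, plan: WindowPlan = WindowPlan(), mode: str = "max") -> dict:
    """Windowed Q50 family over the eleven partial Hamming windows.

    Returns Q50 of window 2 and window 10 (1-based), the minimum Q50 over
    inner windows 2-10, and ``Q50_n``: the 1-based index of the inner
    window with the highest Q50 (``mode="max"``, the default) or lowest
    (``mode="min"``); ties break toward the lowest index.
    """
    if mode not in ("max", "min"):
        raise ValueError(f"unknown Q50_n mode: {mode!r}")
    segments = partial_windows(clip, plan)
    q50s = {}
    for i in INNER_WINDOWS:
        spec = energy_spectrum(segments[i - 1], clip.sample_rate)
        q50s[i] = spectral_quantile(spec, 0.5)
    pick = max if mode == "max" else min
    # ties -> lowest window index (first win in ascending iteration order)
    q50_n = pick(q50s, key=q50s.get)
    return {
        "Q50_2": q50s[2],
        "Q50_10": q50s[10],
        "Q50_min": min(q50s.values()),
        "Q50_n": int(q50_n),
    }


def _frame_energy_spectra(clip: AudioClip, plan: WindowPlan):
    return [energy_spectrum(f, clip.sample_rate) for f in consecutive_windows(clip, plan)]


def q50w(clip: AudioClip, plan: WindowPlan = WindowPlan()) -> float:
    """Q50 of the bin-wise average energy spectrum over consecutive frames."""
    specs = _frame_energy_spectra(clip, plan)
    mean_values = np.mean([s.values for s in specs], axis=0)
    return spectral_quantile(Spectrum(freqs=specs[0].freqs, values=mean_values), 0.5)


def q25_mean(clip: AudioClip, plan: WindowPlan = WindowPlan()) -> float:
    """Per-frame 25% spectral energy quantile, averaged over frames."""
    specs = _frame_energy_spectra(clip, plan)
    return float(np.mean([spectral_quantile(s, 0.25) for s in specs]))


def sf_mean(clip: AudioClip, plan: WindowPlan = WindowPlan()) -> float:
    """Per-frame spectral flatness, averaged over consecutive frames."""
    specs = _frame_energy_spectra(clip, plan)
    return float(np.mean([spectral_flatness(s) for s in specs]))


def sf_q50(clip: AudioClip) -> float:
    """Flatness of the total-signal energy spectrum divided by its Q50 [1/Hz]."""
    spec = energy_spectrum(clip.samples, clip.sample_rate)
    return spectral_flatness(spec) / spectral_quantile(spec, 0.5)


def _normalized_xcorr(frame: np.ndarray, min_lag: int, max_lag: int) -> float:
    """Max normalized cross-correlation of a frame with itself over a lag range.

    r(tau) = sum x[n] x[n+tau] / sqrt(sum x[0:N-tau]^2 * sum x[tau:N]^2),
    i.e. the cosine similarity of the two overlapping segments, which is
    unbiased by the shrinking overlap (a plain biased autocorrelation
    penalizes long lags and caps the harmonicity of clean tones).
    """
    x = frame - np.mean(frame)
    n = x.size
    # full linear autocorrelation via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(x, nfft)
    acorr = np.fft.irfft(spec.real**2 + spec.imag**2, nfft)[:n]
    sq = x**2
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    total = csum[-1]
    if total <= 0.0:
        return 0.0
    lags = np.arange(min_lag, min(max_lag, n - 2) + 1)
    head = total - (csum[-1] - csum[n - lags])  # sum over x[0:N-tau]
    tail = total - csum[lags]  # sum over x[tau:N]
    denom = np.sqrt(head * tail)
    valid = denom > 0
    if not np.any(valid):
        return 0.0
    return float(np.max(acorr[lags[valid]] / denom[valid]))


def hnr(clip: AudioClip, floor_pitch: float = 75.0, ceil_pitch: float = 1000.0) -> float:
    """Harmonics-to-noise ratio in dB from frame-wise autocorrelation.

    Each frame (two floor-pitch periods long, 50% hop) contributes
    ``10 * log10(r / (1 - r))`` where r is the maximum normalized
    autocorrelation in the lag range [1/ceil_pitch, 1/floor_pitch]
    seconds; the clip's HNR is the mean over frames.  This is a
    harmonicity measure in the autocorrelation family, not a bit-exact
    clone of any external tool.
    """
    fs = clip.sample_rate
    frame_len = int(round(2 * fs / floor_pitch))
    hop = frame_len // 2
    if clip.n_samples < frame_len + hop:
        raise InsufficientSamplesError(
            "clip too short for two harmonicity analysis frames at the floor pitch"
        )
    min_lag = max(1, int(np.floor(fs / ceil_pitch)))
    max_lag = int(np.ceil(fs / floor_pitch))
    n_frames = (clip.n_samples - frame_len) // hop + 1
    eps = 1e-12
    vals = []
    for i in range(n_frames):
        frame = clip.samples[i * hop : i * hop + frame_len]
        r = np.clip(_normalized_xcorr(frame, min_lag, max_lag), eps, 1.0 - eps)
        vals.append(10.0 * np.log10(r / (1.0 - r)))
    return float(np.mean(vals))


def cpp(clip: AudioClip, min_quef_s: float = 1.0 / 1000.0, max_quef_s: float = 1.0 / 60.0) -> float:
    """Cepstral peak prominence in dB (optional; off the statistical path).

    The real cepstrum of the log-magnitude (dB) spectrum is searched for
    its peak in the quefrency range [1/1000, 1/60] s; CPP is the peak
    height above a linear regression trend fitted over that range.
    Amplitude scaling shifts the log spectrum by a constant, which lands
    in the DC cepstral bin, so CPP is scale-invariant.
    """
    x = clip.samples
    fs = clip.sample_rate
    mag = np.abs(np.fft.fft(x))
    if not np.any(mag > 0):
        raise DegenerateSignalError("all-zero clip has no cepstrum")
    log_db = 20.0 * np.log10(np.maximum(mag, 1e-300))
    ceps = np.real(np.fft.ifft(log_db))
    quef = np.arange(x.size) / fs
    lo = int(np.ceil(min_quef_s * fs))
    hi = min(int(np.floor(max_quef_s * fs)), x.size // 2)
    if hi <= lo + 2:
        raise InsufficientSamplesError("clip too short for the cepstral search range")
    window = slice(lo, hi + 1)
    coeffs = np.polyfit(quef[window], ceps[window], 1)
    k_peak = lo + int(np.argmax(ceps[window]))
    trend_at_peak = np.polyval(coeffs, quef[k_peak])
    return float(ceps[k_peak] - trend_at_peak)


def compute_parameter_vector(
    clip: AudioClip,
    plan: WindowPlan = WindowPlan(),
    *,
    flux_reduce: str = "mean",
    q50n_mode: str = "max",
    hnr_floor_pitch: float = 75.0,
    include_cpp: bool = False,
) -> dict:
    """All 14 aperiodic parameters for one squeal, as a name -> value dict.

    Deterministic for a fixed clip and configuration.  Errors from member
    computations are re-raised with the parameter name attached.
    """
    out: dict = {}

    def _compute(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    total_spec = _compute("PF", lambda: energy_spectrum(clip.samples, clip.sample_rate))
    out["PF"] = _compute("PF", lambda: peak_frequency(total_spec))
    out["Q50"] = _compute("Q50", lambda: spectral_quantile(total_spec, 0.5))
    out.update(_compute("Q50_partials", lambda: q50_partials(clip, plan, mode=q50n_mode)))
    out["Q50W"] = _compute("Q50W", lambda: q50w(clip, plan))
    out["Q25"] = _compute("Q25", lambda: q25_mean(clip, plan))
    out["Dur"] = _compute("Dur", lambda: duration(clip))
    out["SF"] = _compute("SF", lambda: sf_mean(clip, plan))
    out["SF_Q50"] = _compute(
        "SF_Q50", lambda: spectral_flatness(total_spec) / out["Q50"]
    )
    out["Flux"] = _compute(
        "Flux",
        lambda: spectral_flux(
            [magnitude_spectrum(f, clip.sample_rate) for f in consecutive_windows(clip, plan)],
            reduce=flux_reduce,
        ),
    )
    out["RMSI"] = _compute("RMSI", lambda: rmsi(clip))
    out["HNR"] = _compute("HNR", lambda: hnr(clip, floor_pitch=hnr_floor_pitch))
    if include_cpp:
        out["CPP"] = _compute("CPP", lambda: cpp(clip))
    return {k: out[k] for k in PARAMETER_NAMES + (("CPP",) if include_cpp else ())}


class SquealFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping a sequence of clips to a parameter table.

    ``transform`` accepts an iterable of :class:`~squealkit.audio.AudioClip`
    and returns a :class:`pandas.DataFrame` with one row per clip (indexed
    by clip id) and one column per parameter.  ``fit`` is stateless and
    exists for pipeline compatibility.

    Parameters
    ----------
    n_partial, frame_len, overlap_frac, taper :
        Windowing configuration; see :class:`~squealkit.windows.WindowPlan`.
    flux_reduce : {"mean", "sum"}
        Whether flux averages or sums the per-pair squared differences.
    q50n_mode : {"max", "min"}
        Whether ``Q50_n`` points at the inner window with the highest or
        lowest Q50.
    hnr_floor_pitch : float
        Lowest candidate fundamental for the harmonicity lag search [Hz].
    include_cpp : bool
        Also compute cepstral peak prominence (excluded from statistics).
    """

    def __init__(
        self,
        n_partial: int = 11,
        frame_len: int = 1024,
        overlap_frac: float = 0.5,
        taper: str = "hamming",
        flux_reduce: str = "mean",
        q50n_mode: str = "max",
        hnr_floor_pitch: float = 75.0,
        include_cpp: bool = False,
    ):
        self.n_partial = n_partial
        self.frame_len = frame_len
        self.overlap_frac = overlap_frac
        self.taper = taper
        self.flux_reduce = flux_reduce
        self.q50n_mode = q50n_mode
        self.hnr_floor_pitch = hnr_floor_pitch
        self.include_cpp = include_cpp

    def _plan(self) -> WindowPlan:
        return WindowPlan(
            n_partial=self.n_partial,
            frame_len=self.frame_len,
            overlap_frac=self.overlap_frac,
            taper=self.taper,
        )

    def fit(self, X=None, y=None):
        self.plan_ = self._plan()  # validates the window configuration
        return self

    def transform(self, X):
        import pandas as pd

        plan = self._plan()
        rows = []
        index = []
        for clip in X:
            rows.append(
                compute_parameter_vector(
                    clip,
                    plan,
                    flux_reduce=self.flux_reduce,
                    q50n_mode=self.q50n_mode,
                    hnr_floor_pitch=self.hnr_floor_pitch,
                    include_cpp=self.include_cpp,
                )
            )
            index.append(clip.id)
        return pd.DataFrame(rows, index=pd.Index(index, name="clip_id"))
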