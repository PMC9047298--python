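"""Synthetic squeal generator: harmonic stack + noise with a tunable roll-off.

Real squeals are high-pitched, rough harmonic sounds with broadband
noise; after vocal fold surgery their spectral energy condenses into
the low frequencies.  The generator reproduces these signatures with a
minimal model: a linear fundamental-frequency contour carrying a stack
of harmonics whose amplitudes roll off above a corner frequency, slow
independent random amplitude modulation per harmonic (the roughness /
instability of the voice), plus white Gaussian noise at a controlled
SNR.  Lowering the roll-off corner emulates the post-surgery loss of
high-frequency energy.  Because the per-harmonic modulation perturbs
each bin's share of the normalized spectrum multiplicatively, spectra
concentrated into few bins (low corner) show larger frame-to-frame
normalized differences — the same mechanism by which reduced
high-frequency energy raises spectral flux in real post-surgery
squeals.

Nonlinear phenomena of real pig voice (subharmonics, biphonation,
deterministic chaos) are deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from squealkit.audio import AudioClip, peak_normalize
from squealkit.screening import SquealRecord

__all__ = ["SquealModel", "generate_squeal", "generate_cohort", "SquealSynthesizer"]

logger = logging.getLogger(__name__)

#: Per-rater probabilities of noise scores 0/1/2 used for simulated ratings.
RATING_PROBS = (0.7, 0.25, 0.05)


@dataclass(frozen=True)
class SquealModel:
    """Parameters of one synthetic squeal.

    Parameters
    ----------
    f0_start, f0_end : float
        Fundamental frequency contour endpoints in Hz (linear sweep);
        both must be positive.
    n_harmonics : int
        Number of harmonics in the stack (those above Nyquist are
        dropped).
    rolloff_cutoff : float
        Corner frequency in Hz above which harmonic amplitudes are
        attenuated; the knob that emulates pre- vs post-surgery spectra.
    rolloff_db_per_octave : float
        Attenuation slope above the corner, in dB per octave.
    am_instability : float
        Log-amplitude SD of the slow random modulation applied
        independently to each harmonic (0 = perfectly steady voice).
    am_rate_hz : float
        Rate of the amplitude modulation in control points per second.
    noise_snr_db : float
        Harmonic-to-noise power ratio over the whole clip, in dB.
    duration_s : float
        Clip duration in seconds; at least 0.3 s so that generated
        squeals pass duration screening.
    amplitude_envelope : {"hann", "flat"}
        Overall amplitude shape of the clip.
    seed : int
        Seed of the squeal's private random stream (noise and harmonic
        phases); the clip is fully determined by model + seed.
    """

    f0_start: float = 1200.0
    f0_end: float = 1250.0
    n_harmonics: int = 18
    rolloff_cutoff: float = 8000.0
    rolloff_db_per_octave: float = 24.0
    am_instability: float = 0.25
    am_rate_hz: float = 40.0
    noise_snr_db: float = 10.0
    duration_s: float = 0.5
    amplitude_envelope: str = "hann"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0_start <= 0 or self.f0_end <= 0:
            raise ValueError("f0 contour must stay positive")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if self.rolloff_cutoff <= 0:
            raise ValueError("rolloff_cutoff must be positive")
        if self.duration_s < 0.3:
            raise ValueError("duration_s must be >= 0.3 s (screening floor)")
        if self.amplitude_envelope not in ("hann", "flat"):
            raise ValueError(f"unknown envelope: {self.amplitude_envelope!r}")
        if self.am_instability < 0 or self.am_rate_hz <= 0:
            raise ValueError("amplitude modulation parameters must be nonnegative")


def harmonic_amplitude(model: SquealModel, harmonic: int) -> float:
    """Amplitude of one harmonic under the roll-off envelope.

    Unit amplitude below the corner frequency; above it, attenuated by
    ``rolloff_db_per_octave`` per octave of the harmonic's mean frequency
    over the corner.
    """
    f_mean = harmonic * 0.5 * (model.f0_start + model.f0_end)
    if f_mean <= model.rolloff_cutoff:
        return 1.0
    octaves = np.log2(f_mean / model.rolloff_cutoff)
    return float(10.0 ** (-model.rolloff_db_per_octave * octaves / 20.0))


def generate_squeal(model: SquealModel, sample_rate: int = 44100) -> AudioClip:
    """Render one synthetic squeal as a peak-normalized mono clip.

    The harmonic stack follows the linear f0 contour (each harmonic k at
    k times the instantaneous fundamental) with random initial phases;
    harmonics whose maximum frequency exceeds Nyquist are dropped.
    White Gaussian noise is added at ``noise_snr_db`` (power ratio over
    the whole clip), the amplitude envelope is applied, and the result
    is scaled to peak 1.  Fully deterministic given model and seed.
    """
    rng = np.random.default_rng(model.seed)
    n = int(round(model.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    # phase integral of the linear contour: f(t) = f0_start + (f0_end - f0_start) t/T
    sweep = (model.f0_end - model.f0_start) / model.duration_s
    base_phase = 2.0 * np.pi * (model.f0_start * t + 0.5 * sweep * t**2)
    f0_max = max(model.f0_start, model.f0_end)
    nyquist = sample_rate / 2.0
    harmonic = np.zeros(n)
    # slow random amplitude modulation, independent per harmonic: control
    # points at am_rate_hz, linearly interpolated, lognormal in amplitude
    n_ctrl = max(2, int(np.ceil(model.duration_s * model.am_rate_hz)) + 1)
    t_ctrl = np.linspace(0.0, model.duration_s, n_ctrl)
    for k in range(1, model.n_harmonics + 1):
        if k * f0_max >= nyquist:
            logger.debug("harmonic %d above Nyquist; dropped", k)
            continue
        amp = harmonic_amplitude(model, k)
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        if model.am_instability > 0:
            wobble = np.exp(
                np.interp(t, t_ctrl, rng.normal(0.0, model.am_instability, n_ctrl))
            )
        else:
            wobble = 1.0
        harmonic += amp * wobble * np.sin(k * base_phase + phase0)
    sig_power = np.mean(harmonic**2)
    if sig_power > 0:
        noise_power = sig_power * 10.0 ** (-model.noise_snr_db / 10.0)
        noise = rng.normal(0.0, np.sqrt(noise_power), n)
    else:  # all harmonics above Nyquist: noise-only clip
        noise = rng.normal(0.0, 1.0, n)
    samples = harmonic + noise
    if model.amplitude_envelope == "hann":
        samples = samples * np.hanning(n)
    return AudioClip(samples=peak_normalize(samples), sample_rate=sample_rate)


#: Default per-squeal perturbations creating within-group variance:
#: multiplicative lognormal factors (relative SD).  ``f0_scale`` scales
#: both contour endpoints coherently (a squeal pitched higher keeps its
#: sweep proportional); ``noise_snr_db`` jitter is additive in dB.
DEFAULT_JITTER = {
    "f0_scale": 0.05,
    "rolloff_cutoff": 0.10,
    "duration_s": 0.15,
    "noise_snr_db": 2.0,  # additive SD in dB
}


def _perturb(model: SquealModel, jitter: dict, rng: np.random.Generator) -> SquealModel:
    updates: dict = {}
    for field_name, sd in jitter.items():
        if field_name == "f0_scale":
            scale = np.exp(rng.normal(0.0, sd))
            updates["f0_start"] = model.f0_start * scale
            updates["f0_end"] = model.f0_end * scale
        elif field_name == "noise_snr_db":
            updates[field_name] = model.noise_snr_db + rng.normal(0.0, sd)
        else:
            updates[field_name] = getattr(model, field_name) * np.exp(rng.normal(0.0, sd))
    if "duration_s" in updates:
        updates["duration_s"] = max(0.3, updates["duration_s"])
    return replace(model, **updates)


def generate_cohort(
    pre_model: SquealModel,
    post_model: SquealModel,
    n_pre: int,
    n_post: int,
    jitter_spec: dict | None = None,
    seed: int = 0,
    sample_rate: int = 44100,
    pig_id: str = "pig1",
) -> list[tuple[AudioClip, SquealRecord]]:
    """Simulate one pig's pre/post squeal sets with metadata.

    Each squeal is rendered from a randomly perturbed copy of its phase's
    model (perturbation SDs in ``jitter_spec``, defaulting to
    :data:`DEFAULT_JITTER`), with noise ratings drawn per rater from
    :data:`RATING_PROBS` and artifact flags set to False.  Deterministic
    given the models, counts and seed.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("need at least one squeal per phase")
    jitter = DEFAULT_JITTER if jitter_spec is None else jitter_spec
    rng = np.random.default_rng(seed)
    out: list[tuple[AudioClip, SquealRecord]] = []
    for phase, base, count in (("pre", pre_model, n_pre), ("post", post_model, n_post)):
        for i in range(count):
            model = _perturb(base, jitter, rng)
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clip = generate_squeal(replace(model, seed=clip_seed), sample_rate)
            clip_id = f"{pig_id}_{phase}_{i:03d}"
            clip = replace(clip, id=clip_id)
            ratings = tuple(rng.choice(3, size=3, p=RATING_PROBS))
            record = SquealRecord(
                clip_id=clip_id,
                pig_id=pig_id,
                phase=phase,
                duration=clip.duration_s,
                ratings=ratings,
                artifact=False,
            )
            out.append((clip, record))
    return out


class SquealSynthesizer:
    """Convenience generator for pre/post cohorts of several pigs.

    Parameters
    ----------
    pre_model, post_model : SquealModel
        Phase templates; the post model typically lowers
        ``rolloff_cutoff`` to emulate the loss of high-frequency energy.
    counts : dict
        pig_id -> (n_pre, n_post) analyzed-squeal counts.
    jitter_spec : dict or None
        Per-squeal perturbation SDs (see :data:`DEFAULT_JITTER`).
    sample_rate : int
        Output sampling rate in Hz (default 44100).
    """

    def __init__(
        self,
        pre_model: SquealModel = SquealModel(rolloff_cutoff=8000.0),
        post_model: SquealModel = SquealModel(rolloff_cutoff=2000.0),
        counts: dict[str, tuple[int, int]] | None = None,
        jitter_spec: dict | None = None,
        sample_rate: int = 44100,
    ):
        self.pre_model = pre_model
        self.post_model = post_model
        self.counts = {"pig1": (20, 20)} if counts is None else counts
        self.jitter_spec = jitter_spec
        self.sample_rate = sample_rate

    def sample(self, seed: int = 0) -> list[tuple[AudioClip, SquealRecord]]:
        """Generate all pigs' cohorts; deterministic given the seed."""
        root = np.random.SeedSequence(seed)
        out: list[tuple[AudioClip, SquealRecord]] = []
        for (pig_id, (n_pre, n_post)), child in zip(
            sorted(self.counts.items()), root.spawn(len(self.counts))
        ):
            out.extend(
                generate_cohort(
                    self.pre_model,
                    self.post_model,
                    n_pre,
                    n_post,
                    jitter_spec=self.jitter_spec,
                    seed=int(child.generate_state(1)[0] % (2**31 - 1)),
                    sample_rate=self.sample_rate,
                    pig_id=pig_id,
                )
            )
        return out
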