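# Methods

This note documents the models, numerical choices and limitations of
`squealkit`: what exactly each parameter computes, what the synthetic
squeal generator does and does not emulate, and where the design was
genuinely open.

## Signal model and preprocessing

The unit of analysis is one squeal: a mono waveform at its recording
rate (44.1 kHz throughout this package's defaults). Because absolute
sound pressure is not available from free-roaming enclosure recordings,
every clip is scaled so its absolute peak is exactly 1; stereo input is
reduced to mono by keeping the left channel. Normalization is applied
per squeal, including after segment extraction, so each clip is
self-contained (whether to normalize per squeal or once per recording
session is underdetermined; per-squeal is the only self-contained
choice and is what RMSI is defined against). Integer PCM is converted
to float by dividing by the dtype's maximum magnitude. All-zero signals
are rejected rather than silently propagated, since peak normalization
and every spectral parameter are undefined on them.

Segment bounds are half-open `[start, end)` in seconds with sample
index `floor(t·fs)`: unambiguous and composable (adjacent segments
tile without overlap).

## Windowing

Three schemes cover all parameters:

* **total** — a rectangular window over the entire squeal, giving the
  maximal frequency resolution (bin width `fs/N`).
* **partial** — eleven evenly spaced Hamming windows. "Evenly spaced"
  is read as contiguous, non-overlapping windows of length
  `L = floor(N/11)` starting at `0, L, 2L, …`, with the trailing
  `N − 11·L` samples unused. The source tradition for these windowed
  parameters does not fix a window length or overlap; contiguous tiling
  is the simplest reading that keeps "the second window" and "the nine
  inner windows" well defined. Window indices are 1-based; inner
  windows are 2–10.
* **consecutive** — fixed 1024-sample frames with 50% overlap
  (hop 512) and a Hamming taper; frame count is
  `floor((N − 1024)/512) + 1` with every frame fully inside the signal.
  1024/50% are the settings used for all consecutive-window parameters
  uniformly; the taper for these frames is not dictated by the
  parameter definitions, and Hamming (the only taper the parameter set
  names anywhere) is applied by default, with `rectangular` available.

## Spectra and spectral parameters

Spectra are one-sided with FFT length equal to the window length (no
zero padding). Energy spectra are `|DFT|²` with the conventional
doubling of interior bins, so total spectral energy equals `N·Σx²`
(Parseval); the DC bin is included in all spectral sums, as nothing in
the parameter definitions excludes it.

* **Spectral quantile** (Q50, Q25 and the windowed family): the
  frequency of the smallest bin whose cumulative energy reaches
  `q · total`. No interpolation — the parameter is defined as a
  dividing frequency and downstream statistics only use its ordering.
  Ties (a bin exactly reaching the threshold) resolve to that bin.
* **PF**: argmax of the total energy spectrum, ties toward the lowest
  frequency (determinism).
* **Q50_n**: 1-based index of the inner partial window (2–10) with the
  *highest* Q50, ties toward the lowest index. The alternative reading
  — the window where high harmonics are *least* dominant, i.e. the
  minimum — is retained behind `q50n_mode="min"`.
* **Spectral flatness**: geometric over arithmetic mean of energy
  values; any zero bin makes it exactly 0 (no flooring), and a constant
  spectrum returns exactly 1. Note that white *noise* does not have
  flatness 1: the periodogram of Gaussian noise has i.i.d. exponential
  bin energies, whose geometric/arithmetic mean ratio converges to
  `exp(−γ) ≈ 0.561` (γ the Euler–Mascheroni constant). Tests assert
  this value, not 1, for noise clips; flatness 1 is reserved for a
  literally flat spectrum.
* **Spectral flux**: each consecutive frame's *magnitude* spectrum is
  normalized to sum to 100 (percent magnitude), the bin-wise squared
  differences of neighboring frames are summed over frequency, and the
  pair sums are averaged over time. Averaging over pairs (rather than a
  grand sum) keeps the value comparable across squeal durations; the
  grand-sum variant is available via `flux_reduce="sum"`. Percent
  normalization makes flux invariant to per-frame loudness, so it
  measures change of spectral *shape* only.

## HNR and CPP

HNR is an autocorrelation-family harmonicity measure, not a bit-exact
clone of any external analysis tool. Frames are two floor-pitch periods
long (default floor 75 Hz → ~26.7 ms at 44.1 kHz) with 50% hop. Per
frame, the lag range [1/1000 s, 1/75 s] is searched for the maximum of
the *unbiased* normalized cross-correlation (cosine similarity of the
two overlapping segments) — a plain biased autocorrelation shrinks with
lag and would cap the harmonicity of even a clean tone. With
`r` clipped to `(ε, 1−ε)` (ε = 1e−12), the frame contributes
`10·log10(r/(1−r))` dB and the clip's HNR is the frame mean. Only
qualitative behavior is promised (strongly tonal ≫ noise); on aperiodic
voices the parameter is known to behave counter-intuitively (a
spectrally condensed noisy signal can score *higher* because the best
correlation lag becomes more consistent), and the synthetic experiments
reproduce that tendency.

CPP takes the real cepstrum of the dB magnitude spectrum of the whole
clip, searches the quefrency range [1/1000, 1/60] s, and reports the
peak height above a linear regression trend fitted over that same
range. Amplitude scaling shifts the log spectrum by a constant that
lands in the DC cepstral bin, so CPP is scale-invariant. CPP is off the
statistical path (it presumes a detectable fundamental) and is computed
only on request.

## Screening

Inclusion requires duration ≥ 0.3 s, mean rater noise score ≤ 1.00
(inclusive — a mean of exactly 1.00 stays in), and no artifact flag.
Rules are evaluated in the order duration → rating → artifact and the
first failing rule labels the exclusion. Rating means are compared as
exact rationals (`Fraction`), because three raters produce means on a
1/3 grid and float arithmetic at the 1.00 boundary would be fragile.

## Statistics

Each animal is analyzed independently (animals differ in age, sex and
baseline "vocoprint"; pooling them answers a different question). Per
parameter, a one-sided Wilcoxon rank-sum test compares pre vs post with
the direction encoding the expected change:

| direction | parameters |
|---|---|
| decrease | PF, Q50, Q50₂, Q50₁₀, Q50_min, Q50W, Q25, Dur, Q50_n, HNR |
| increase | SF, SF_Q50, Flux, RMSI |

All directions are configurable. Two entries deserve comment: Q50_n has
no principled direction (it is a window index) and "decrease" is a
default, not a claim; SF_Q50 couples a numerator expected to rise with
a denominator expected to fall, and the default follows the numerator.
The directions for the interpretable parameters encode the core
expectation that post-surgery spectral energy condenses into low
frequencies while the voice becomes noisier and less stable.

The test uses the exact null distribution when the combined sample size
is ≤ 20 and there are no ties (making the small-sample enumeration
oracle in the tests an exact check), and otherwise the normal
approximation with tie and continuity correction. Fully constant data
across both groups yields p = 1 with a warning.

Within each animal the 14 p-values receive the Benjamini–Yekutieli
step-up correction at α = 0.05: adjusted
`p_(i) → min(1, step-up min of m·c(m)·p_(i)/i)` with
`c(m) = Σ_{i≤m} 1/i`. BY is valid under arbitrary dependence, which
matters because the parameters are largely functionals of the same
spectra. Significance tiers are marked at adjusted p ≤ 0.05 and
≤ 0.001.

## The synthetic squeal generator

The generator exists so every pipeline stage is testable without
recordings. One squeal is:

```
s(t) = env(t) · [ Σ_k a_k · w_k(t) · sin(k·φ(t) + θ_k) + n(t) ]
```

* `φ(t)` — phase of a linear f0 contour, default 1200 → 1250 Hz over
  the clip (squeal fundamentals sit in the low kHz; a mild rise is a
  common contour shape).
* `a_k` — roll-off envelope: 1 below the corner frequency
  (`rolloff_cutoff`), attenuated by `rolloff_db_per_octave` (default
  24 dB/oct) above it, evaluated at the harmonic's mean frequency.
  Harmonics reaching Nyquist are dropped. Lowering the corner from
  8 kHz (healthy default) to 2 kHz emulates the post-surgery loss of
  high-frequency energy.
* `w_k(t)` — slow random amplitude modulation, independent per
  harmonic: lognormal with log-SD `am_instability` (default 0.25),
  linearly interpolated between control points at 40 Hz. This is the
  roughness/instability of the voice, and it is the main carrier of
  spectral flux: under percent normalization, a spectrum concentrated
  into few bins (low corner) turns the same relative per-bin
  fluctuation into larger squared differences — the mechanism by which
  reduced high-frequency energy raises flux in real post-surgery
  squeals. An early design that carried all inter-frame change via a
  strong f0 sweep got this direction wrong (a sweep moves high
  harmonics across many bins and so favors *broad* spectra); the
  amplitude-instability model is both more realistic for rough voices
  and reproduces the documented directionality.
* `n(t)` — white Gaussian noise at `noise_snr_db` (default 10 dB,
  power ratio over the whole clip — enclosure recordings of a
  free-roaming animal are far from clean), added before the overall
  Hann amplitude envelope.

Default duration is 0.5 s (clips of at least 0.3 s pass screening by
construction); the FDR-calibration simulations use 0.3 s clips, the
shortest admissible squeal, to keep the problem size moderate.

Cohorts perturb the template per squeal: one lognormal factor (SD 5%)
scales the whole f0 contour coherently (so sweep rate stays
proportional to pitch — independent endpoint jitter would make
within-group flux variance an artifact of the jitter spec), corner
frequency SD 10%, duration SD 15% (floored at 0.3 s), SNR jitter
2 dB additive. Ratings are drawn per rater from P(0, 1, 2) =
(0.7, 0.25, 0.05), so occasional squeals fail noise screening, and
artifact flags are false.

What the generator does **not** emulate: subharmonics, biphonation and
deterministic chaos (all present in real pig voice), formant structure,
room acoustics, overlapping vocalizations, and rater behavior tied to
actual audio content. Passing tests therefore show that the pipeline
recovers the modeled spectral signatures with correct error control;
they do not certify performance on recordings whose irregularities fall
outside this model.

## Simulation scale and numerical choices

* FDR-under-the-null check: 200 simulated animals, 20/20 squeals of
  0.3 s each, identical pre/post models; the realized false-discovery
  proportion is compared to the nominal 5% plus twice its Monte Carlo
  standard error. Power/direction check: 50 replicate cohorts at the
  8 kHz → 2 kHz corner drop, 20/20 squeals at default duration. The
  acceptance script uses 40 null animals and 25 power replicates —
  sizes chosen so a full from-scratch rerun stays in the minutes range
  while keeping binomial noise on the reported proportions small.
* All random streams derive from explicit integer seeds via numpy
  `SeedSequence`; cohort members get spawned child seeds, so results
  are reproducible and order-independent.
* Degenerate inputs fail loudly: all-zero clips, zero-energy spectra,
  zero-total flux frames and empty samples raise typed errors rather
  than returning sentinel values.
* Quantile/argmax tie-breaks are all "lowest bin/index", making every
  parameter deterministic.

## Known limitations

* HNR and CPP are re-implementations in their algorithm families, not
  numerically interchangeable with other tools' outputs.
* The partial-window reading (contiguous tiling) is one defensible
  interpretation of "eleven evenly spaced windows"; absolute-duration
  or overlapping readings would change Q50₂/Q50₁₀/Q50_min/Q50_n values.
* The hypothesis directions for Q50_n and SF_Q50 are conventions, not
  derivations; both are configurable.
* Real squeal screening involves a human judgment ("is this a squeal?")
  upstream of everything implemented here.
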