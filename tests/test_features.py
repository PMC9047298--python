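import numpy as np
import pytest

from squealkit.audio import AudioClip
from squealkit.features import (
    PARAMETER_NAMES,
    SquealFeatureExtractor,
    compute_parameter_vector,
    cpp,
    duration,
    hnr,
    q25_mean,
    q50_partials,
    q50w,
    rmsi,
    sf_mean,
)
from squealkit.synth import SquealModel, generate_squeal
from squealkit.windows import WindowPlan

FS = 44100
EULER_MASCHERONI_FLATNESS = float(np.exp(-np.euler_gamma))  # periodogram flatness of white noise


class TestDurationAndRmsi:
    def test_duration_is_n_over_fs(self):
        assert duration(AudioClip(np.ones(22050), FS)) == pytest.approx(0.5)
        assert duration(AudioClip(np.ones(44100), FS)) == pytest.approx(1.0)

    def test_square_wave_rmsi_is_one(self):
        x = np.tile([1.0, -1.0], 500)
        assert rmsi(AudioClip(x, FS)) == pytest.approx(1.0)

    def test_full_scale_sine_rmsi_is_inv_sqrt2(self, tone_clip):
        assert rmsi(tone_clip()) == pytest.approx(1 / np.sqrt(2), abs=1e-3)


class TestQ50Partials:
    def test_stationary_tone_all_windows_agree(self, tone_clip):
        res = q50_partials(tone_clip(duration_s=1.0))
        assert res["Q50_min"] == res["Q50_2"] == res["Q50_10"]
        assert res["Q50_n"] == 2  # all tied -> lowest inner index

    def test_rising_chirp_later_windows_higher(self, chirp_clip):
        res = q50_partials(chirp_clip(f_start=1000.0, duration_s=1.0))
        assert res["Q50_10"] > res["Q50_2"]
        assert res["Q50_n"] == 10

    def test_window_index_range(self, noise_clip):
        for seed in range(5):
            res = q50_partials(noise_clip(seed=seed))
            assert res["Q50_n"] in range(2, 11)

    def test_q50_min_bounded_by_named_windows(self, noise_clip):
        res = q50_partials(noise_clip(seed=42))
        assert res["Q50_min"] <= min(res["Q50_2"], res["Q50_10"])

    def test_min_mode_selects_lowest_inner_window(self, chirp_clip):
        res = q50_partials(chirp_clip(f_start=1000.0, duration_s=1.0), mode="min")
        assert res["Q50_n"] == 2  # rising chirp: lowest Q50 in earliest window

    def test_window_wise_oracle(self, chirp_clip):
        from squealkit.spectral import energy_spectrum, spectral_quantile
        from squealkit.windows import partial_windows

        clip = chirp_clip(f_start=800.0, duration_s=0.7)
        segs = partial_windows(clip, WindowPlan())
        oracle = {
            i: spectral_quantile(energy_spectrum(segs[i - 1], FS), 0.5) for i in range(2, 11)
        }
        res = q50_partials(clip)
        assert res["Q50_min"] == min(oracle.values())
        assert res["Q50_2"] == oracle[2]
        assert res["Q50_10"] == oracle[10]


class TestConsecutiveParameters:
    def test_stationary_tone_q50w_at_tone_bin(self, tone_clip):
        clip = tone_clip()
        assert q50w(clip) == pytest.approx(24 * FS / 512, abs=FS / 1024)

    def test_single_frame_q50w_equals_frame_q50(self, tone_clip):
        from squealkit.spectral import energy_spectrum, spectral_quantile
        from squealkit.windows import consecutive_windows

        clip = tone_clip(duration_s=1024 / FS)
        frame = consecutive_windows(clip, WindowPlan())[0]
        assert q50w(clip) == spectral_quantile(energy_spectrum(frame, FS), 0.5)

    def test_q25_matches_per_frame_oracle(self, noise_clip):
        from squealkit.spectral import energy_spectrum, spectral_quantile
        from squealkit.windows import consecutive_windows

        clip = noise_clip(seed=3)
        plan = WindowPlan()
        expected = np.mean(
            [
                spectral_quantile(energy_spectrum(w, FS), 0.25)
                for w in consecutive_windows(clip, plan)
            ]
        )
        assert q25_mean(clip, plan) == pytest.approx(expected)

    def test_q50w_matches_binwise_mean_oracle(self, noise_clip):
        from squealkit.spectral import Spectrum, energy_spectrum, spectral_quantile
        from squealkit.windows import consecutive_windows

        clip = noise_clip(seed=8)
        specs = [energy_spectrum(w, FS) for w in consecutive_windows(clip, WindowPlan())]
        mean_spec = Spectrum(specs[0].freqs, np.mean([s.values for s in specs], axis=0))
        assert q50w(clip) == spectral_quantile(mean_spec, 0.5)

    def test_flatness_separates_noise_from_tone(self, noise_clip, tone_clip):
        sf_noise = sf_mean(noise_clip(duration_s=1.5))  # > 50 frames
        sf_tone = sf_mean(tone_clip())
        # white-noise periodogram flatness converges to exp(-gamma) ~ 0.561
        assert sf_noise == pytest.approx(EULER_MASCHERONI_FLATNESS, abs=0.05)
        assert sf_tone <= 0.1
        assert sf_noise > 5 * sf_tone


class TestHnr:
    def test_closed_form_r_half_is_zero_db(self):
        r = 0.5
        assert 10 * np.log10(r / (1 - r)) == pytest.approx(0.0)

    def test_full_scale_sine_strongly_harmonic(self, tone_clip):
        assert hnr(tone_clip(freq=800.0, duration_s=0.4)) >= 25.0

    def test_white_noise_weakly_harmonic(self, noise_clip):
        assert hnr(noise_clip(seed=0)) <= 5.0

    def test_invariant_to_amplitude_scaling(self, tone_clip):
        loud = tone_clip(freq=500.0)
        quiet = AudioClip(0.05 * loud.samples, FS, "quiet")
        assert hnr(loud) == pytest.approx(hnr(quiet), rel=1e-9)


class TestCpp:
    def test_periodic_stack_beats_noise(self, noise_clip):
        voiced = generate_squeal(SquealModel(noise_snr_db=25, am_instability=0.1, seed=1))
        assert cpp(voiced) > cpp(noise_clip())

    def test_invariant_to_amplitude_doubling(self, tone_clip):
        clip = tone_clip(freq=700.0)
        doubled = AudioClip(2.0 * clip.samples, FS, "double")
        assert cpp(clip) == pytest.approx(cpp(doubled), rel=1e-9)


class TestParameterVector:
    def test_deterministic(self, noise_clip):
        clip = noise_clip(seed=5)
        assert compute_parameter_vector(clip) == compute_parameter_vector(clip)

    def test_stationary_tone_frequency_parameters_coincide(self, tone_clip):
        f = 24 * FS / 512
        pv = compute_parameter_vector(tone_clip())
        assert pv["PF"] == pytest.approx(f, abs=2 * FS / 22050)
        assert pv["Q50"] == pytest.approx(f, abs=2 * FS / 22050)
        assert pv["Q50W"] == pytest.approx(f, abs=FS / 1024)

    def test_vector_has_all_names_and_optional_cpp(self, noise_clip):
        clip = noise_clip()
        assert tuple(compute_parameter_vector(clip)) == PARAMETER_NAMES
        with_cpp = compute_parameter_vector(clip, include_cpp=True)
        assert tuple(with_cpp) == PARAMETER_NAMES + ("CPP",)

    def test_invariants_on_random_synthetic_squeals(self):
        rng = np.random.default_rng(2024)
        nyquist = FS / 2
        for _ in range(30):
            model = SquealModel(
                f0_start=float(rng.uniform(600, 2000)),
                f0_end=float(rng.uniform(600, 2000)),
                rolloff_cutoff=float(rng.uniform(1000, 10000)),
                noise_snr_db=float(rng.uniform(5, 25)),
                duration_s=float(rng.uniform(0.3, 0.6)),
                seed=int(rng.integers(2**31)),
            )
            pv = compute_parameter_vector(generate_squeal(model))
            assert pv["Q50_min"] <= min(pv["Q50_2"], pv["Q50_10"])
            assert pv["Q50_n"] in range(2, 11)
            assert 0.0 <= pv["SF"] <= 1.0
            assert pv["Flux"] >= 0.0
            assert 0.0 < pv["RMSI"] <= 1.0
            assert pv["Dur"] > 0.0
            for name in ("PF", "Q50", "Q50_2", "Q50_10", "Q50_min", "Q50W", "Q25"):
                assert 0.0 <= pv[name] <= nyquist


class TestExtractorEstimator:
    def test_transform_returns_indexed_frame(self, tone_clip, noise_clip):
        clips = [tone_clip(id="a"), noise_clip(id="b")]
        table = SquealFeatureExtractor().fit().transform(clips)
        assert list(table.index) == ["a", "b"]
        assert list(table.columns) == list(PARAMETER_NAMES)

    def test_get_set_params_round_trip(self):
        est = SquealFeatureExtractor(frame_len=512)
        params = est.get_params()
        assert params["frame_len"] == 512
        est.set_params(flux_reduce="sum")
        assert est.flux_reduce == "sum"

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = SquealFeatureExtractor(q50n_mode="min")
        assert clone(est).q50n_mode == "min"
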