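import numpy as np
import pytest

from squealkit.audio import AudioClip

FS = 44100


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def tone_clip():
    """Factory for pure-tone clips; default frequency is aligned to both the
    1024-sample frame grid and the 512-sample hop so consecutive frames are
    sample-identical (a truly stationary tone)."""

    def make(freq=24 * FS / 512, duration_s=0.5, amplitude=1.0, fs=FS, id="tone"):
        n = int(round(duration_s * fs))
        t = np.arange(n) / fs
        return AudioClip(amplitude * np.sin(2 * np.pi * freq * t), fs, id)

    return make


@pytest.fixture
def noise_clip():
    def make(duration_s=0.5, fs=FS, seed=0, id="noise"):
        rng = np.random.default_rng(seed)
        return AudioClip(rng.normal(size=int(round(duration_s * fs))), fs, id)

    return make


@pytest.fixture
def chirp_clip():
    """Linear chirp rising one octave from the given start frequency."""

    def make(f_start=24 * FS / 512, duration_s=0.5, fs=FS, id="chirp"):
        n = int(round(duration_s * fs))
        t = np.arange(n) / fs
        phase = 2 * np.pi * (f_start * t + f_start * t**2 / (2 * duration_s))
        return AudioClip(np.sin(phase), fs, id)

    return make
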