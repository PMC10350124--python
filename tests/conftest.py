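import numpy as np
import pytest

from vocsim import AudioSignal, SynthSpec, synth_stimulus

FS = 16000.0


@pytest.fixture(scope="session")
def am_tone():
    """1 kHz tone, 100% sinusoidally amplitude-modulated at 10 Hz, 1 s."""
    t = np.arange(int(FS)) / FS
    mod = 1.0 + np.sin(2 * np.pi * 10.0 * t)
    return AudioSignal(mod * np.sin(2 * np.pi * 1000.0 * t), FS), mod


@pytest.fixture(scope="session")
def harmonic_stimulus():
    """AM harmonic complex with its analytically known modulator."""
    return synth_stimulus(SynthSpec(f0=200.0, n_harmonics=10, am_rate=8.0,
                                    duration=1.0, fs=FS, seed=11))


@pytest.fixture(scope="session")
def white_noise():
    rng = np.random.default_rng(3)
    return AudioSignal(rng.standard_normal(int(2 * FS)), FS)
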