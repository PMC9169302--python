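import numpy as np
import pytest

from wingbeat import NoiseModel, default_profiles, synth_corpus, synth_wingbeat


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_corpus():
    """Four-class corpus, 30 recordings per profile, ~10% invalid."""
    return synth_corpus(n_per_class=30, invalid_fraction=0.1, seed=7)


@pytest.fixture(scope="session")
def clean_corpus():
    """Small all-valid corpus for bench and cascade tests."""
    return synth_corpus(n_per_class=25, invalid_fraction=0.0, seed=11)


@pytest.fixture(scope="session")
def one_flight(profiles):
    return synth_wingbeat(profiles[0], noise=NoiseModel(), seed=5)


def direct_periodogram(x: np.ndarray, fs: float = 9603.0) -> tuple[np.ndarray, np.ndarray]:
    """Independent single-window Hann periodogram oracle (density scaling)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))  # periodic Hann
    spectrum = np.fft.rfft(x * w)
    density = (np.abs(spectrum) ** 2) / (fs * np.sum(w**2))
    density[1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, density
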