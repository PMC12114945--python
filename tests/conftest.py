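import numpy as np
import pytest

from emgonset import EmgSignal

FS = 1500.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture
def tone():
    """Factory for pure-tone EmgSignals."""

    def _tone(freq_hz: float, duration_s: float = 2.0, amplitude: float = 1.0, fs: float = FS):
        t = np.arange(int(round(duration_s * fs))) / fs
        return EmgSignal(samples=amplitude * np.sin(2 * np.pi * freq_hz * t), fs=fs)

    return _tone


@pytest.fixture
def noise_signal():
    """Factory for seeded white-noise EmgSignals."""

    def _noise(seed: int, n: int = 4096, fs: float = FS):
        rng = np.random.default_rng(seed)
        return EmgSignal(samples=rng.standard_normal(n), fs=fs)

    return _noise
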