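import numpy as np
import pytest

from singscore import canonical_template


@pytest.fixture(scope="session")
def song():
    """The built-in two-verse template (64 notes, 128 eighth slots)."""
    return canonical_template()


@pytest.fixture(scope="session")
def verse():
    """A single verse (32 notes) — cheaper for audio round trips."""
    return canonical_template(verses=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def harmonic_tone(f0_hz: float, duration_s: float, rate_hz: float = 48000.0,
                  amps=(1.0, 0.5, 0.25, 0.125), amplitude: float = 0.4) -> np.ndarray:
    """Steady harmonic complex used as tracker ground truth in several tests."""
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    x = sum(a * np.sin(2 * np.pi * (h + 1) * f0_hz * t) for h, a in enumerate(amps))
    return amplitude * np.asarray(x) / sum(amps)
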