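import numpy as np
import pytest

from fndtrace import ModulationConfig, SpectrumModel


@pytest.fixture
def default_config() -> ModulationConfig:
    """2 Hz / 20 mT square modulation, depth 0.10, 60 s at 20 samples/s."""
    return ModulationConfig()


@pytest.fixture
def clean_model() -> SpectrumModel:
    """Spectral model with no background and no drift (pure FND emission)."""
    return SpectrumModel.default(
        brightness_per_conc=1000.0, background_level=0.0, drift_fraction=0.0
    )


def lockin_amplitude(x: np.ndarray, fs: float, f: float) -> float:
    """Brute-force lock-in: multiply by sin/cos at f, integrate.

    Independent oracle for the FFT-bin amplitude (one-sided, counts/s);
    agrees with the DFT bin exactly when f lies on the frequency grid.
    """
    n = x.size
    t = np.arange(n) / fs
    c = np.sum(x * np.cos(2.0 * np.pi * f * t))
    s = np.sum(x * np.sin(2.0 * np.pi * f * t))
    return 2.0 * np.hypot(c, s) / n * fs
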