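import numpy as np
import pytest

from finpam.calibrated_audio import CalibrationSpec


@pytest.fixture
def calib() -> CalibrationSpec:
    """AURAL-style calibration: S=-164, G=22, M=84 (constant +58 dB)."""
    return CalibrationSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def white_noise(rng, duration_s: float, fs: float, floor_db: float) -> np.ndarray:
    """White pressure noise with the given spectral density (dB re 1 µPa²/Hz)."""
    n = int(round(duration_s * fs))
    sigma = np.sqrt(10.0 ** (floor_db / 10.0) * fs / 2.0)
    return rng.normal(0.0, sigma, n)
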