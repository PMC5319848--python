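import numpy as np
import pytest

from sarcometrics import OpticalModelParams, SarcomereGroundTruth


@pytest.fixture
def clean_optics() -> OpticalModelParams:
    """Noiseless confocal-like optics."""
    return OpticalModelParams(noise_sd=0.0)


@pytest.fixture
def ideal_optics() -> OpticalModelParams:
    """Noiseless, PSF-free optics: the analytic limit of the forward model."""
    return OpticalModelParams(psf_sigma=0.0, noise_sd=0.0)


@pytest.fixture
def uniform_fibril() -> SarcomereGroundTruth:
    """Six uniform sarcomeres with a visible H band (SL 2.2, TFL 0.98)."""
    return SarcomereGroundTruth.from_sl_tfl([2.2] * 6, [0.98] * 6, "fib0")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
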