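import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from senequant import make_default_library_truth
from senequant.simulate import default_grid, generate_background_spectrum
from senequant.spectra import Spectrum

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth_library():
    return make_default_library_truth()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def zero_background(grid):
    return Spectrum(grid, np.zeros_like(grid), {"role": "background"})


@pytest.fixture
def smooth_background(grid):
    """Noiseless smooth imaging-solution background."""
    return generate_background_spectrum(grid, 0.05, np.random.default_rng(0), noise_sd=0.0)
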