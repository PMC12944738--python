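import numpy as np
import pytest
from hypothesis import settings

from lpkin import FilterConfig, SyntheticPressConfig, simulate_press

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def fcfg() -> FilterConfig:
    """Default filtering chain at 50 fps."""
    return FilterConfig(fs=50.0)


@pytest.fixture(scope="session")
def noiseless_press():
    """One clean three-rep simulated press trial (default study conditions)."""
    return simulate_press(SyntheticPressConfig(seed=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
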