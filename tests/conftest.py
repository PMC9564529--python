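import numpy as np
import pytest

from econeeds.synthetic_data import LandscapeParams, generate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """60x60 two-epoch landscape with drivers and red line (seed 11)."""
    params = LandscapeParams(rows=60, cols=60, change_fraction=0.1, seed=11)
    return generate_landscape(params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
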