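import numpy as np
import pytest

from connectscape.covariates import standardize_stack
from connectscape.raster import Raster
from connectscape.synthetic import LandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def small_stack():
    """An 80x80 synthetic covariate stack shared across tests."""
    return generate_landscape(LandscapeConfig(rows=80, cols=80, seed=7,
                                              n_villages=8))


@pytest.fixture(scope="session")
def prepared(small_stack):
    return standardize_stack(small_stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def uniform_surface():
    """5x5 uniform-resistance raster, 30 m cells."""
    return Raster(np.ones((5, 5)), cell_size=30.0)
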