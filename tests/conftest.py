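import numpy as np
import pytest

from rsdna import SolutionSpec, default_params, default_t_grid


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def coarse_grid():
    """A 5 C temperature grid, enough for curve-shape assertions."""
    return default_t_grid(0.0, 95.0, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20220411)


@pytest.fixture(scope="session")
def pool_12n():
    """The 12-mer pool at the concentrated defect-statistics conditions."""
    return SolutionSpec(L=12, c_mass=25.0, na_molar=1.0)


@pytest.fixture(scope="session")
def pool_12n_dilute():
    """The 12-mer pool at the UV-melting concentration."""
    return SolutionSpec(L=12, c_mass=0.04, na_molar=1.0)
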