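import numpy as np
import pytest

from dbtlsim import default_pathway, generate_parameters, simulate_steady_state
from dbtlsim.design_space import DesignGrid, simulate_landscape


@pytest.fixture(scope="session")
def spec():
    return default_pathway()


@pytest.fixture(scope="session")
def params(spec):
    return generate_parameters(spec, seed=0)


@pytest.fixture(scope="session")
def wildtype(params):
    return simulate_steady_state(params)


@pytest.fixture(scope="session")
def toy_grid(spec):
    """27-design toy space over three enzymes and three levels."""
    return DesignGrid(enzymes=("rA", "rD", "rG"), levels=(0.5, 1.0, 2.0))


@pytest.fixture(scope="session")
def toy_landscape(params, toy_grid):
    return simulate_landscape(params, toy_grid)


@pytest.fixture(scope="session")
def mid_grid(spec):
    """81-design space over four enzymes, used for learning-loop tests."""
    return DesignGrid(enzymes=("rA", "rC", "rD", "rG"), levels=(0.5, 1.0, 2.0))


@pytest.fixture(scope="session")
def mid_landscape(params, mid_grid):
    return simulate_landscape(params, mid_grid)
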