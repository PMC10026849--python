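import numpy as np
import pytest

from oligoniche.datatypes import GridSpec
from oligoniche.synthetic import gen_vessel_network


@pytest.fixture(scope="session")
def vessel_net():
    """Moderately sized branched network shared across proximity tests."""
    return gen_vessel_network(domain=(2000.0, 2000.0), n_branches=40, step=20.0, seed=7)


@pytest.fixture
def small_grid():
    return GridSpec((-500.0, 500.0), (-500.0, 500.0), spacing=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
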