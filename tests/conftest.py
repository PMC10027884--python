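import numpy as np
import pytest

from arcdose.geometry import GridSpec
from arcdose.synthetic import Phantom, make_pdd_table


@pytest.fixture(scope="session")
def pdd():
    return make_pdd_table()


@pytest.fixture(scope="session")
def water_cylinder():
    return Phantom(kind="cylinder")


@pytest.fixture()
def small_grid():
    """Coarse evaluation cube for fast end-to-end tests."""
    return GridSpec.centred_cube(80.0, 4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
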