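import numpy as np
import pytest

from deerdescramble import forward_model as fm


@pytest.fixture(scope="session")
def small_grids():
    return fm.small_grids()


@pytest.fixture(scope="session")
def small_kernel(small_grids):
    dgrid, tgrid = small_grids
    return fm.build_kernel(dgrid, tgrid)


@pytest.fixture(scope="session")
def small_config(small_grids):
    dgrid, tgrid = small_grids
    return fm.default_config(dgrid, tgrid)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
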