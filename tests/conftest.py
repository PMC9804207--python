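import numpy as np
import pytest

from funcalib.fdata import make_grid


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def fine_grid():
    return make_grid(401)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
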