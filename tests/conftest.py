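import numpy as np
import pytest
from hypothesis import settings

from polyblock.combinatorics import get_table

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def table24():
    return get_table(2, 4)


@pytest.fixture(scope="session")
def table34():
    return get_table(3, 4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
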