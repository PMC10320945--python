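import numpy as np
import pytest

from dosefluence.geometry import build_all_operators
from dosefluence.phantom import generate_case
from dosefluence.profiles import get_profile


@pytest.fixture(scope="session")
def micro_profile():
    return get_profile("micro")


@pytest.fixture(scope="session")
def micro_case(micro_profile):
    return generate_case(11, micro_profile.phantom)


@pytest.fixture(scope="session")
def micro_ops(micro_case):
    return build_all_operators(micro_case.grid, micro_case.beams)


@pytest.fixture(scope="session")
def tiny_profile():
    return get_profile("tiny")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
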