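import numpy as np
import pytest

import surfreho as sr


@pytest.fixture(scope="session")
def ico2():
    return sr.build_icosphere(2, 100.0)


@pytest.fixture(scope="session")
def ico3():
    return sr.build_icosphere(3, 100.0)


@pytest.fixture(scope="session")
def ring1_ico3(ico3):
    return sr.build_neighborhoods(ico3, "ring1")


@pytest.fixture(scope="session")
def ring2_ico3(ico3):
    return sr.build_neighborhoods(ico3, "ring2")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
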