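import numpy as np
import pytest

import tracegas as tg


@pytest.fixture(scope="session")
def h2():
    return tg.get_gas("H2")


@pytest.fixture(scope="session")
def co():
    return tg.get_gas("CO")


@pytest.fixture(scope="session")
def mean_seawater():
    return tg.get_matrix("mean_seawater")


@pytest.fixture(scope="session")
def freshwater():
    return tg.get_matrix("freshwater")


@pytest.fixture(scope="session")
def munida_vial():
    return tg.get_vial("munida")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
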