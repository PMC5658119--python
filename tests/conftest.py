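import numpy as np
import pytest

from nucmap import CircularSequenceMap, trp1ars1_fixture


@pytest.fixture(scope="session")
def trp1():
    return trp1ars1_fixture()


@pytest.fixture(scope="session")
def trp1_map(trp1):
    return trp1.map


@pytest.fixture
def toy_circle():
    return CircularSequenceMap("toy", 500)


@pytest.fixture
def toy_linear():
    return CircularSequenceMap("toylin", 500, topology="linear")


@pytest.fixture
def rng():
    return np.random.default_rng(20171026)
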