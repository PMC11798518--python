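import numpy as np
import pytest

from mcspec.physics import get_matrix
from mcspec.xrf import DetectorModel, GeometryModel


@pytest.fixture(scope="session")
def det():
    return DetectorModel()


@pytest.fixture(scope="session")
def geom():
    return GeometryModel()


@pytest.fixture(scope="session")
def hap():
    return get_matrix("HAP")


@pytest.fixture(scope="session")
def hap_b():
    return get_matrix("HAP_B")


@pytest.fixture(scope="session")
def whit():
    return get_matrix("WHIT")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
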