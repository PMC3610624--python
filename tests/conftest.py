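import numpy as np
import pytest

from bulbnet.cells import build_granule, build_mitral


@pytest.fixture(scope="session")
def mitral():
    return build_mitral()


@pytest.fixture(scope="session")
def granule():
    return build_granule()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
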