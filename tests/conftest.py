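import numpy as np
import pytest

from baculopolya.pas_model import ModelSpec


@pytest.fixture(scope="session")
def improved():
    return ModelSpec.preset("improved2020")


@pytest.fixture(scope="session")
def initial():
    return ModelSpec.preset("initial2003")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
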