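import numpy as np
import pytest

from avmtf.filterbanks import GammatoneBank, ModulationFilterbank


@pytest.fixture(scope="session")
def mfb():
    return ModulationFilterbank()


@pytest.fixture(scope="session")
def gamma_bank():
    return GammatoneBank()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
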