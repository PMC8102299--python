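import numpy as np
import pytest

from hydronmr import synthetic_data as sd


@pytest.fixture(scope="session")
def nt():
    return sd.get_preset("N. tigrina")


@pytest.fixture(scope="session")
def ua():
    return sd.get_preset("U. antarctica")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
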