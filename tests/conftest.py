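import numpy as np
import pytest

from arsmr.instrument_catalog import load_instruments
from arsmr.phenotyping import default_reference_model


@pytest.fixture(scope="session")
def instruments():
    return load_instruments()


@pytest.fixture(scope="session")
def ref_model():
    return default_reference_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
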