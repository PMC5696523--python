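import numpy as np
import pytest
from hypothesis import settings

from dualgene import load_matrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
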