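import numpy as np
import pytest

from pba.fixtures import make_toy_models


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toys():
    return make_toy_models()
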