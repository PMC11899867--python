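import numpy as np
import pytest

from asvasc.layers import ROIMask


@pytest.fixture
def full_roi():
    return ROIMask(np.ones((304, 304), dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
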