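import numpy as np
import pytest

from olfontogeny import DriveMap, SynthConfig


@pytest.fixture
def cfg():
    return SynthConfig()


@pytest.fixture
def drive():
    return DriveMap()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
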