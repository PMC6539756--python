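import numpy as np
import pytest

from braggloc.bragg_dose import BeamPulse, StoppingModel


@pytest.fixture
def model():
    return StoppingModel()


@pytest.fixture
def beam100():
    return BeamPulse(e0=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)
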