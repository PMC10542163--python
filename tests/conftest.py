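import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_membrane():
    """A 1 um straight horizontal membrane polyline (nm)."""
    return np.column_stack([np.linspace(0.0, 1000.0, 51), np.zeros(51)])
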