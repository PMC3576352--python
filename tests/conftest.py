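import numpy as np
import pytest

from petquant import PetVolume


@pytest.fixture
def block_volume():
    """9x9x1 volume: background SUV 1 with a central 3x3 block of SUV 8."""
    vals = np.ones((9, 9, 1))
    vals[3:6, 3:6, 0] = 8.0
    return PetVolume(vals, spacing=(4.0, 4.0, 4.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
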