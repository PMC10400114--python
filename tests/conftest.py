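import numpy as np
import pytest

from funcnet.confounds import TissueMask, VolumeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def unit_complete_4():
    W = np.ones((4, 4)) - np.eye(4)
    return W


@pytest.fixture
def random_volume(rng):
    """Small 4D volume with a whole-brain mask."""
    data = rng.normal(100.0, 5.0, size=(6, 6, 5, 20))
    vols = VolumeSeries(data=data, voxel_size=3.0, tr=2.0)
    mask = TissueMask(probabilities=np.ones((6, 6, 5)), label="whole-brain")
    return vols, mask
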