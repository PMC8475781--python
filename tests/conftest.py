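import numpy as np
import pytest

from demandmri import glm as glm_mod
from demandmri import synthetic as syn


@pytest.fixture(scope="session")
def hrf():
    return glm_mod.build_hrf()


@pytest.fixture(scope="session")
def small_phantom():
    """Compact default-profile phantom used across tests."""
    return syn.make_phantom(grid_dims=(16, 16, 12))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, drift-free phantom for exact-recovery checks."""
    return syn.make_phantom(grid_dims=(16, 16, 12), noise_sd=0.0,
                            drift=(0.0, 0.0), participant_scale_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
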