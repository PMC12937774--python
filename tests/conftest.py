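import numpy as np
import pytest

from gvscreen.features import CENTRAL_CHANNELS
from gvscreen.simulate import CohortConfig, simulate_cohort
from gvscreen.stimuli import build_default_library


@pytest.fixture(scope="session")
def library():
    return build_default_library()


@pytest.fixture(scope="session")
def mini_cohort(library):
    """Tiny 2+2-subject cohort over the first 12 stimuli (13-ch montage)."""
    cfg = CohortConfig(n_hc=2, n_pd=2, n_trials=12,
                       channel_names=CENTRAL_CHANNELS, master_seed=7)
    return simulate_cohort(cfg, library)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
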