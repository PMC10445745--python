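import numpy as np
import pytest

import ovfield
from ovfield.pipeline import run_pipeline

MASTER_SEED = 11


@pytest.fixture(scope="session")
def bundle_small():
    return ovfield.simulate("small", seed=MASTER_SEED)


@pytest.fixture(scope="session")
def bundle_default():
    return ovfield.simulate("default", seed=MASTER_SEED)


@pytest.fixture(scope="session")
def result_default(bundle_default):
    """One full pipeline run on the default preset, shared across tests."""
    return run_pipeline(bundle_default, seed=MASTER_SEED, with_clustering=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
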