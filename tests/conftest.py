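import numpy as np
import pytest

from ithpipe import mutsig, simdata


@pytest.fixture(scope="session")
def reference():
    return mutsig.load_signature_matrix()


@pytest.fixture(scope="session")
def clean_cfg():
    """Noiseless study conditions: no strand-bias outliers or contaminants."""
    return simdata.SimConfig(seed=1, strand_bias_outlier_rate=0.0, contaminant_rate=0.0)


@pytest.fixture(scope="session")
def sim_patient(clean_cfg):
    """(variants, expression, segments, truth) for one noiseless patient."""
    return simdata.simulate_patient(clean_cfg, "P01")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
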