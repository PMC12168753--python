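import numpy as np
import pytest

import divn2o as d
from divn2o.micn import KMAX_NAMES
from divn2o.pipeline import DEFAULT_TRUE_FPD, DEFAULT_TRUE_KMAX


@pytest.fixture(scope="session")
def default_params():
    return d.default_params()


@pytest.fixture(scope="session")
def true_params(default_params):
    """Synthetic ground truth, offset from the packaged defaults."""
    return default_params.with_kmax(dict(DEFAULT_TRUE_KMAX))


@pytest.fixture(scope="session")
def true_fpd():
    return d.DiversityFactor(coefficients=dict(DEFAULT_TRUE_FPD))


@pytest.fixture(scope="session")
def uniform_fpd():
    """One shared negative power-law coefficient for every pathway."""
    return d.DiversityFactor(coefficients={n: -0.2 for n in KMAX_NAMES})


@pytest.fixture(scope="session")
def endmembers():
    return d.default_endmembers()


@pytest.fixture(scope="session")
def site_forcing():
    return d.gen_site_forcing(36, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
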