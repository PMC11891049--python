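import numpy as np
import pytest

from ivimrad import StudyConfig, run_study
from ivimrad.cohort import CohortConfig
from ivimrad.schemes import site_bvalue_scheme
from ivimrad.signal import IVIMParams, ivim_signal


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """One seeded default-scale study (302 patients) shared by all tests
    that assert study-level properties; by far the most expensive fixture."""
    cfg = StudyConfig(seed=1)
    return run_study(cfg, tmp_path_factory.mktemp("default_study"))


@pytest.fixture(scope="session")
def tiny_config():
    return StudyConfig(
        cohort=CohortConfig(site_counts={"A": (2, 2), "B": (2, 2), "C": (2, 2)}),
        seed=7)


def make_decay(f_p, D_p, D_t, site="C", variant=1, s0=1.0):
    scheme = site_bvalue_scheme(site, variant)
    s = ivim_signal(IVIMParams(f_p, D_p, D_t, s0), scheme.b_values)
    return s, scheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
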