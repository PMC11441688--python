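import numpy as np
import pytest

from gied_entropy.censoring import CensoringScheme, ProgressiveSample, make_scheme, sample_pc2
from gied_entropy.model import GIEDParams, quantile


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def half_half():
    """The simulation-study truth: beta = lam = 0.5."""
    return GIEDParams(beta=0.5, lam=0.5)


@pytest.fixture(scope="session")
def sim_sample():
    """One medium PC-II sample from GIED(0.7, 2.0), scheme a, n=40, m=25."""
    p = GIEDParams(beta=0.7, lam=2.0)
    scheme = make_scheme("a", 40, 25)
    rng = np.random.default_rng(7)
    return sample_pc2(lambda u: quantile(u, p), scheme, rng)


@pytest.fixture(scope="session")
def small_complete_sample():
    """Complete sample of n = 10 from GIED(1, 1) for posterior-grid checks."""
    p = GIEDParams(beta=1.0, lam=1.0)
    rng = np.random.default_rng(11)
    scheme = CensoringScheme(n=10, m=10, R=(0,) * 10)
    return sample_pc2(lambda u: quantile(u, p), scheme, rng)
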