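import numpy as np
import pytest

from siteadapt import DomainPair, ShiftConfig, gen_domain_shift


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_shift():
    """A small shifted two-domain problem: (pair, target truth)."""
    cfg = ShiftConfig(n_source=40, n_target=40, dims=8, seed=7)
    src, tgt, truth = gen_domain_shift(cfg)
    return DomainPair(Xs=src.X.T, ys=src.labels, Xt=tgt.X.T), truth
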