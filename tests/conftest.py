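"""Shared fixtures: the default synthetic study fixture and one full run.

Everything is generated programmatically; the heavier objects are
session-scoped so the pipeline is assembled once for the whole suite.
"""

import numpy as np
import pytest

import hicsampler as hs
from hicsampler import mcmc_sampler as ms
from hicsampler import mrf_model


@pytest.fixture(scope="session")
def default_truth():
    """200-bin map, 3 TADs, 2 loops, depth 5e5."""
    return hs.make_truth(seed=1)


@pytest.fixture(scope="session")
def default_contacts(default_truth):
    return hs.simulate_counts(default_truth, seed=2)


@pytest.fixture(scope="session")
def balanced(default_contacts):
    return hs.ice_balance(default_contacts, max_iter=500, tol=1e-10)


@pytest.fixture(scope="session")
def decay_model(default_contacts, balanced):
    return hs.fit_decay(default_contacts, balanced.bias, 0.1, seed=3)


@pytest.fixture(scope="session")
def full_spec(balanced):
    return mrf_model.build_spec(balanced.normalized, mask=balanced.bias.mask)


@pytest.fixture(scope="session")
def default_run(default_contacts, balanced, decay_model, full_spec):
    """Two-chain adaptive run; 10 thinned draws = 500 post-freeze sweeps."""
    cfg = ms.SamplerConfig(n_samples=10, seed=7)
    return ms.run(default_contacts, balanced.bias, decay_model, full_spec, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
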