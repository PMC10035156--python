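import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from agbgrowth import (PFT, MCMCConfig, PosteriorSample, TruthSpec,
                       default_truth, normalize_climate, simulate_records)


@pytest.fixture(scope="session")
def z0():
    """Reference climate: MAP 800 mm, MAT 7 C -> (0, 0)."""
    return normalize_climate(800.0, 7.0)


@pytest.fixture(scope="session")
def truths():
    return {pft: default_truth(pft) for pft in PFT}


@pytest.fixture(scope="session")
def bd_data():
    """Small broadleaf-deciduous synthetic dataset shared across fit tests."""
    return simulate_records(TruthSpec.single("bd", 300, seed=11))


@pytest.fixture(scope="session")
def fast_config():
    """Short sampler settings for tests that need a real fit but not a
    fully converged one."""
    return MCMCConfig(chains=2, iterations=1000, seed=7)


def make_sample(theta, n_draws=50, n_chains=2, jitter=0.0, seed=0):
    """A PosteriorSample whose draws are copies of ``theta`` (optionally
    jittered); handy for exercising prediction/aggregation deterministically."""
    theta = np.asarray(theta, dtype=float)
    rng = np.random.default_rng(seed)
    draws = np.tile(theta, (n_draws, n_chains, 1))
    if jitter:
        draws = draws + rng.normal(0.0, jitter, size=draws.shape)
        draws[..., 6] = np.abs(draws[..., 6]) + 1e-6
    return PosteriorSample(draws)


@pytest.fixture(scope="session")
def degenerate_sample():
    """All draws identical: mu = 400, r = 4, sigma = 0.5, no climate effect."""
    return make_sample([400.0, 0.0, 0.0, 4.0, 0.0, 0.0, 0.5])
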