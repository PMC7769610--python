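import warnings

import numpy as np
import pytest

from microjoint import (SimulationConfig, simulate_joint_dataset, fit_joint)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study: fast enough to fit repeatedly in tests."""
    return SimulationConfig(n_subjects=80, k_samples=5)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_joint_dataset(small_config, seed=42)


@pytest.fixture(scope="session")
def fitted_sim():
    """A moderate simulated study with a converged joint-model fit.

    Shared across inference/prediction/evaluation tests to keep the suite
    fast; N=150 subjects with 6 samples each is enough for the posterior
    to concentrate near the generating values.
    """
    cfg = SimulationConfig(n_subjects=150, k_samples=6)
    dataset, truth = simulate_joint_dataset(cfg, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        post = fit_joint(dataset, chains=2, warmup=700, draws=400,
                         seed=3)
    return cfg, dataset, truth, post


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
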