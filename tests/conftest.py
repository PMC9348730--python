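"""Shared fixtures: small, fast scenario configurations and cohorts."""

import numpy as np
import pytest

import lifemvmr as lm


@pytest.fixture(scope="session")
def small_config():
    """Two-liability scenario shrunk for fast unit tests."""
    return lm.preset("two_liabilities").scaled(
        n_reps=4, n_sample=4000, seed=123)


@pytest.fixture(scope="session")
def small_effects(small_config):
    rng = np.random.default_rng(7)
    return lm.draw_snp_effects(small_config, rng)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_effects):
    rng = np.random.default_rng(8)
    return lm.simulate_cohort(small_effects, small_config, "exposure", rng)


@pytest.fixture(scope="session")
def small_gwas(small_cohort):
    return lm.run_gwas(small_cohort, ["X1", "X2"])
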