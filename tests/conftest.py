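import numpy as np
import pytest

from svcohort import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.default_config(
        n_samples=60,
        seed=11,
        sv_counts={"DEL": 20, "DUP": 10, "INS": 6},
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_calls(small_truth, small_config):
    alpha, bravo = small_config.caller_profiles
    return (
        simulate.emulate_caller(small_truth, alpha),
        simulate.emulate_caller(small_truth, bravo),
    )


@pytest.fixture(scope="session")
def big_truth():
    """~300 samples, ~3,000 SNPs, ~300 SVs: used by the kinship-ordering and
    parent-offspring acceptance checks."""
    config = simulate.default_config(
        n_samples=300,
        n_founders=80,
        seed=29,
        sv_counts={"DEL": 150, "DUP": 150},
    )
    return simulate.simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
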