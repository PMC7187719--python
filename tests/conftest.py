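import numpy as np
import pytest

from morphnet import CohortConfig, build_covariance_network, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact four-cell cohort reused by several test modules."""
    return generate_cohort(CohortConfig(n_subjects_per_cell=12, seed=11))


@pytest.fixture(scope="session")
def modular_ct_network(small_cohort):
    """CT covariance network of one cohort cell (68 regions, 12 subjects)."""
    return build_covariance_network(small_cohort.table("CT", "HC", "3T"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
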