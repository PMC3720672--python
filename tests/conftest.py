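import numpy as np
import pytest

from hrvsurv import CohortSimSpec, simulate_cohort
from hrvsurv.reference import cohort_from_table_counts


@pytest.fixture(scope="session")
def table_cohort():
    """Patient-level expansion of the published descriptive counts."""
    return cohort_from_table_counts()


@pytest.fixture(scope="session")
def sim_cohort():
    """One medium synthetic cohort shared by read-only tests."""
    return simulate_cohort(CohortSimSpec(n=1000, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
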