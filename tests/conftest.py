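import numpy as np
import pytest

from lymphokinetics import CohortConfig, generate_cohort
from lymphokinetics.kinetics import compute_endpoints


@pytest.fixture(scope="session")
def cohort():
    """A mid-size default cohort shared across tests."""
    return generate_cohort(CohortConfig(n_patients=150, seed=3))


@pytest.fixture(scope="session")
def endpoints(cohort):
    table, exclusions = compute_endpoints(cohort.series().values())
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
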