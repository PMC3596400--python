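import numpy as np
import pytest

from gfrnet.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-record default-condition cohort shared across tests."""
    return generate_cohort(CohortConfig(n=200, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
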