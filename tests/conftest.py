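import numpy as np
import pytest

from moodpulse import CohortConfig, GeneratorParams, simulate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A small default-parameter cohort shared across read-only tests."""
    return simulate_cohort(CohortConfig(n_users=40, n_days=7, seed=11))


@pytest.fixture(scope="session")
def medium_bundle():
    """A cohort big enough for model training, 75% annotation missingness."""
    return simulate_cohort(
        CohortConfig(n_users=150, n_days=14, seed=5),
        GeneratorParams(annotation_missingness=0.75),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)

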