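import numpy as np
import pytest

from groupwise_risk import CohortConfig, generate_base_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """5 groups x 400 individuals, elevated prevalence for stable small fits."""
    cfg = CohortConfig(
        n_groups=5, group_sizes=400, prevalence=0.10, group_effect_sd=0.3, seed=7
    )
    return generate_base_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions: 21 groups x 2000, K = 0.0321."""
    return generate_base_cohort(CohortConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
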