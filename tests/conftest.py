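import numpy as np
import pytest

from connsae.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted effects."""
    return generate_cohort(CohortConfig(n_per_group=10, seed=42))


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with strong planted effects on a few nodes and one coupling."""
    cfg = CohortConfig(
        n_per_group=15,
        effect_nodes=[("struct", 3), ("struct", 11), ("func", 5)],
        effect_size=2.0,
        symptom_coupling=[("struct_strength_3", "inattention_t", 6.0)],
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
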