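import pytest

from dietgap.synthetic import CohortConfig, build_food_library, generate_cohort


@pytest.fixture(scope="session")
def library():
    """Default food library: recipes, mapping, conversion config."""
    return build_food_library(seed=0)


@pytest.fixture(scope="session")
def cohort_bundle():
    """A small generated cohort shared across tests (deterministic)."""
    config = CohortConfig(n_children=120, seed=3)
    return generate_cohort(config)
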