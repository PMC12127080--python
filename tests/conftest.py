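import numpy as np
import pandas as pd
import pytest

from staggerdid import (CohortConfig, ModelSpec, build_treatment_indicator,
                        generate_panel, generate_policy_schedule)

SMALL_COHORTS = ((2013, 3), (2014, 2), (2016, 1))


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Compact cohort preserving the staggered three-cohort calendar."""
    return CohortConfig(n_regions=30, treated_cohorts=SMALL_COHORTS,
                        n_individuals_per_region=25, seed=7)


@pytest.fixture(scope="session")
def small_schedule(small_config):
    return generate_policy_schedule(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_schedule) -> pd.DataFrame:
    panel = generate_panel(small_config, small_schedule)
    return build_treatment_indicator(panel, small_schedule)


@pytest.fixture(scope="session")
def demo_spec() -> ModelSpec:
    return ModelSpec(covariates=("female", "age", "bmi"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
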