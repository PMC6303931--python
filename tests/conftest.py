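import numpy as np
import pytest

from chronocope.synthetic import CohortConfig, Individual, generate_cohort


@pytest.fixture
def default_config() -> CohortConfig:
    return CohortConfig(seed=7)


@pytest.fixture
def small_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_individual(boldness: float, iid: str = "G01F01") -> Individual:
    return Individual(
        id=iid, group_id="G01", boldness=boldness, sex="F", body_weight=150.0
    )
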