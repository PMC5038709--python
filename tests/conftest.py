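import numpy as np
import pytest

import psychstate as ps
from psychstate.config import GeneratorConfig


@pytest.fixture(scope="session")
def default_effects():
    return GeneratorConfig().effective_effects()


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast integration tests: 15 subjects, 5 min each."""
    return GeneratorConfig(
        n_subjects=15,
        class_counts={"E": 4, "A": 4, "N": 7},
        duration_s=300.0,
        window_w=20,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ps.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return ps.features_table(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
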