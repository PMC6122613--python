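import numpy as np
import pytest

from lungdx.ir_features import default_region_map, normalize_cohort
from lungdx.synthetic_cohort import (
    CohortConfig,
    EffectSpec,
    GroupSpec,
    default_config,
    generate_cohort,
)

SMALL_STAGES = {"IA": 12, "IB": 5, "IIA": 4, "IIB": 4, "IIIA": 14, "IIIB": 6, "IV": 15}


def small_config(seed: int = 0, effects=(), background_sd: float = 2.0) -> CohortConfig:
    """A reduced cohort with the study's marker moments, for fast CV tests."""
    groups = [
        GroupSpec("cancer", 60, 0.159, 0.156, 12.1, 7.6, SMALL_STAGES),
        GroupSpec("inflammation", 40, 0.485, 0.237, 4.3, 2.8),
        GroupSpec("control", 40, 0.152, 0.113),
    ]
    return CohortConfig(groups=groups, effects=tuple(effects),
                        background_sd=background_sd, seed=seed)


@pytest.fixture(scope="session")
def region_map():
    return default_region_map()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_config(seed=0))


@pytest.fixture(scope="session")
def default_cohort_normalized(default_cohort):
    return normalize_cohort(default_cohort)


@pytest.fixture(scope="session")
def small_cohort_normalized():
    return normalize_cohort(generate_cohort(small_config(seed=1)))


@pytest.fixture(scope="session")
def one_signal_cohort_normalized():
    """Only the glutamate region separates the groups by construction."""
    return normalize_cohort(generate_cohort(small_config(seed=2, effects=())))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
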