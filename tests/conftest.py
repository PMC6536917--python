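import numpy as np
import pytest

from pathint.cohort import default_group_specs, generate_cohort
from pathint.geometry import ArenaConfig


@pytest.fixture(scope="session")
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort at the study's group sizes, shared across tests."""
    return generate_cohort(default_group_specs(), rng_seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
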