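import numpy as np
import pytest

from gradhier.atlas import default_parcellation
from gradhier.simulate import HierarchySpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def atlas200():
    return default_parcellation(200)


@pytest.fixture(scope="session")
def atlas20():
    return default_parcellation(20)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast end-to-end cohort: 20 parcels, 5 subjects/group, 60 timepoints."""
    config = SimulationConfig(
        n_parcels=20, n_per_group=5, n_timepoints=60, seed=42
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def contracted_cohort():
    """Full-width cohort (P = 200) with a DMN-weighted contraction planted;
    few subjects per group to stay fast."""
    config = SimulationConfig(
        n_parcels=200,
        n_per_group=6,
        n_timepoints=120,
        network_kappa={"Default": 0.6},
        seed=9,
    )
    return simulate_cohort(config)
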