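import numpy as np
import pytest

from supraconnect import (
    CohortDesign,
    IntensityModel,
    RegionSpec,
    build_toy_atlas,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def toy_atlas():
    """8-region toy annotation volume + matching 2-level ontology."""
    return build_toy_atlas(8, (20, 22, 20), 25.0)


@pytest.fixture(scope="session")
def small_design():
    """Compact 4-region design used across modules (fast to simulate)."""
    return CohortDesign(
        regions=[
            RegionSpec(1, 120.0, 0.5, 100.0),
            RegionSpec(2, 80.0, 0.2, 80.0),
            RegionSpec(3, 60.0, 0.35, 40.0),
            RegionSpec(4, 40.0, 0.1, 60.0),
        ],
        dispersion=8.0,
        intensity_model=IntensityModel(correlation=0.6, dual_cervical_dimming=0.5),
        severity_sparing={"moderate": {1: 0.25, 2: 0.4, 3: 0.3, 4: 0.35}},
        n_animals=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_atlas():
    return build_toy_atlas(4, (16, 18, 14), 25.0)


@pytest.fixture(scope="session")
def small_cohort(small_design, small_atlas):
    volume, ontology = small_atlas
    return simulate_cohort(small_design, volume, ontology)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
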