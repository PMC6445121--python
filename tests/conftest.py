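import numpy as np
import pytest

from hmtg.cohort import CohortSpec, default_parcel_specs, generate_cohort, generate_neural
from hmtg.core import build_schedule
from hmtg.strategy_space import cluster_grid, simulate_grid


@pytest.fixture(scope="session")
def schedule():
    return build_schedule(0)


@pytest.fixture(scope="session")
def grid():
    """The full 101x101 grid of simulated behavior (shared; ~10k points)."""
    return simulate_grid()


@pytest.fixture(scope="session")
def zones(grid):
    return cluster_grid(grid)


@pytest.fixture(scope="session")
def cohort_default(zones):
    """Study-sized cohort (24 IA / 5 GA / 21 MO / 7 GR) at the default noise."""
    return generate_cohort(CohortSpec(seed=11), zones)


@pytest.fixture(scope="session")
def cohort_noiseless(zones):
    return generate_cohort(CohortSpec(noise_sd=0.0, seed=12), zones)


@pytest.fixture(scope="session")
def neural_high_snr(cohort_default):
    """Near-noiseless patterns: planted structure should be recovered exactly."""
    return generate_neural(
        cohort_default, default_parcel_specs(), noise_sd_voxel=0.05, seed=21
    )


@pytest.fixture(scope="session")
def neural_default(cohort_default):
    return generate_neural(
        cohort_default, default_parcel_specs(), noise_sd_voxel=1.0, seed=22
    )
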