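import numpy as np
import pytest

from arousalnet.preprocess_io import (
    NetworkPartition,
    ParcellatedTimeSeries,
)
from arousalnet.synthetic_cohort import CohortConfig, generate_spherical_centroids


def small_config(**overrides) -> CohortConfig:
    """Reduced-size cohort configuration for fast tests."""
    base = dict(
        n_delirious=5,
        n_control=5,
        n_regions=40,
        n_networks=4,
        n_timepoints=80,
        n_affected=8,
        peak_rate=3.0,  # bursts per run, scaled with the shorter run
        seed=0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_timeseries(rng):
    """A well-behaved random 60 x 8 series."""
    data = rng.standard_normal((60, 8))
    labels = [f"r{i}" for i in range(8)]
    return ParcellatedTimeSeries("sub-001", "delirious", data, labels, 2.6)


@pytest.fixture
def four_module_partition():
    labels = [f"r{i}" for i in range(8)]
    return NetworkPartition(labels, np.repeat(np.arange(4), 2))


@pytest.fixture(scope="session")
def geometry_100():
    return generate_spherical_centroids(100, seed=7)
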