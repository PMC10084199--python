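import numpy as np
import pytest

from spatialplus import SimConfig, SpatialDataset, build_basis, generate_replicate
from spatialplus.basis import SpatialLocations


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_locs(rng):
    """30 random locations in [0, 10]^2 (general position)."""
    return SpatialLocations(rng.uniform(0, 10, (30, 2)))


@pytest.fixture
def small_basis(small_locs):
    return build_basis(small_locs, k=12)


@pytest.fixture(scope="session")
def replicate_small():
    """One Gaussian replicate at a desk-scale preset (n=120, k=40)."""
    return generate_replicate(SimConfig(n=120, grid=30, k=40), seed=7)


@pytest.fixture(scope="session")
def dataset_small(replicate_small):
    r = replicate_small
    return SpatialDataset(r.locs.coords, r.x, r.y)
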