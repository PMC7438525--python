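import numpy as np
import pytest

from landchange.grids import DEFAULT_SCHEME, GridTransform, LandCoverGrid
from landchange.synthetic import ScenarioConfig, generate_scene_pair


@pytest.fixture(scope="session")
def scene():
    """Moderate synthetic scene shared by read-only tests."""
    config = ScenarioConfig(shape=(100, 100), seed=7)
    return generate_scene_pair(config)


@pytest.fixture
def transform():
    return GridTransform(x0=500_000.0, y0=3_000_000.0, dx=30.0, dy=30.0)


@pytest.fixture
def small_grid(transform):
    rng = np.random.default_rng(0)
    values = rng.choice(DEFAULT_SCHEME.codes, size=(12, 12)).astype(np.int32)
    values[0, 0] = 0  # one nodata cell
    return LandCoverGrid(values=values, transform=transform, epoch="t1")
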