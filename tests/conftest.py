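import numpy as np
import pytest

from popgraph.fixtures import FixtureConfig, make_atlas


@pytest.fixture(scope="session")
def small_cfg() -> FixtureConfig:
    """Miniature grid exercising the same code paths as the full scale."""
    return FixtureConfig(
        grid_shape=(12, 14, 12),
        n_timepoints=60,
        n_regions_per_hemisphere=3,
        n_templates=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_atlas(small_cfg):
    return make_atlas(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
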