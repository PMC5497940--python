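import pandas as pd
import pytest

from oceanhealth import EngineConfig, WorldSpec, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact but complete synthetic world shared across tests."""
    return generate_world(WorldSpec(n_regions=12, rng_seed=11))


@pytest.fixture(scope="session")
def cfg():
    return EngineConfig()


@pytest.fixture()
def cells_one_region():
    """Three equal-area cells in one region, first one coastal."""
    return pd.DataFrame(
        {
            "cell_id": [1, 2, 3],
            "region_id": [1, 1, 1],
            "area_km2": [1.0, 1.0, 1.0],
            "coastal_flag": [True, False, False],
        }
    )
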