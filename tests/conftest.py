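import numpy as np
import pytest

from pahfire.emissions import SECTORS, inventory_from_values
from pahfire.fate_boxmodel import make_environment
from pahfire.gridutil import regular_grid
from pahfire.species_registry import load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def parent_names(registry):
    return registry.parent_names()


@pytest.fixture
def small_grid():
    return regular_grid(4, 8)


def build_inventory(values, species, lat, lon, year=""):
    return inventory_from_values(values, species, lat, lon, year=year)


@pytest.fixture
def toy_inventory(parent_names, small_grid):
    """Small random inventory over the full sector/species/month structure."""
    lat, lon = small_grid
    rng = np.random.default_rng(42)
    values = rng.uniform(0.0, 5.0, size=(len(SECTORS), len(parent_names), 12, len(lat), len(lon)))
    return build_inventory(values, parent_names, lat, lon, year="toy")


@pytest.fixture
def uniform_environment(small_grid):
    lat, lon = small_grid
    shape = (12, len(lat), len(lon))
    monthly = {
        "temperature": np.full(shape, 288.0),
        "oc": np.full(shape, 5.0),
        "bc": np.full(shape, 1.0),
        "oh": np.full(shape, 1.0e6),
        "o3": np.full(shape, 30.0),
        "no3": np.full(shape, 2.5e8),
    }
    return make_environment(lat, lon, monthly)
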