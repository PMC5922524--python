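import numpy as np
import pytest

from bioregions.data import OccurrenceTable, SiteRegistry
from bioregions.synthetic import LandscapeConfig, generate_community, generate_landscape


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_table():
    """Moderately sparse random incidence table (30 sites, 80 species)."""
    r = np.random.default_rng(7)
    inc = (r.random((30, 80)) < 0.25).astype(np.uint8)
    inc[inc.sum(axis=1) == 0, 0] = 1
    return OccurrenceTable([f"s{i:02d}" for i in range(30)],
                           [f"sp{j:02d}" for j in range(80)], inc)


@pytest.fixture()
def scattered_registry():
    r = np.random.default_rng(11)
    n = 40
    return SiteRegistry([f"s{i:02d}" for i in range(n)],
                        r.uniform(-43.0, -40.0, n),
                        r.uniform(-10.0, -7.0, n))


@pytest.fixture(scope="session")
def small_landscape():
    """A 30x30 landscape with 4 planted bands and its community."""
    cfg = LandscapeConfig(n_rows=30, n_cols=30, planted_k=4, smooth_sigma=3.0)
    stack, truth = generate_landscape(cfg, seed=42)
    table, registry = generate_community(stack, truth, n_sites=60,
                                         n_species=250, seed=43)
    return stack, truth, table, registry
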