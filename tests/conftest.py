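import numpy as np
import pandas as pd
import pytest

from recruits.inventory_io import InventoryTable
from recruits.synthetic_forest import (
    ScenarioConfig,
    generate_species_pool,
    simulate_inventory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_scenario(**overrides) -> ScenarioConfig:
    """A 4-plot scaled-down scenario for fast tests."""
    base = dict(
        n_plots=4,
        agb_lost_pct=(0.0, 0.0, 30.0, 60.0),
        n_species=60,
        stems_per_ha=40.0,
        base_recruits_per_year=8.0,
        seed=7,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture
def small_cfg():
    return small_scenario()


@pytest.fixture(scope="module")
def small_bundle():
    """(pool, inventory, disturbance, ground truth) for a small scenario."""
    cfg = small_scenario()
    rng = np.random.default_rng(cfg.seed)
    pool = generate_species_pool(cfg, rng)
    inv, dist, truth = simulate_inventory(pool, cfg, rng)
    return cfg, pool, inv, dist, truth


def toy_inventory(rows, disturbance_year=2000) -> InventoryTable:
    """Build an InventoryTable from (tree, plot, year, dbh, vern, species, alive) tuples."""
    df = pd.DataFrame(
        rows, columns=["tree_id", "plot_id", "year", "dbh_cm", "vernacular", "species", "alive"]
    )
    return InventoryTable(df, disturbance_year=disturbance_year)
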