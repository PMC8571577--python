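"""Synthetic forest-inventory generator with full ground truth.

Emulates a tropical silvicultural experiment: twelve 6.25-ha plots on a
disturbance gradient of 0-60% aboveground biomass (AGB) lost, censused
annually, with a ~600-species pool split into successional guilds.
Recruitment (trees crossing the 10 cm DBH threshold) increases with
disturbance intensity, and the recruit species mix is transiently
enriched in pioneer / light-demanding taxa following a unimodal pulse
that peaks ~15 years after disturbance, with amplitude increasing along
the gradient. Control plots recruit from the background community
throughout.

Degradation operators then emulate the observational imperfections the
analysis must handle: vernacular field names that map ambiguously onto
botanical species (with a known generating association), and a trait
campaign that missed whole species and left some measured species with
missing trait values.

Every stochastic step flows from one :class:`numpy.random.Generator`, so
identical seeds give bit-identical outputs, and the returned
:class:`GroundTruth` suffices to recompute every downstream quantity
exactly when degradation is off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inventory_io import (
    UNRESOLVED,
    INVENTORY_COLUMNS,
    DisturbanceTable,
    InventoryTable,
)
from .taxonomy_resolution import AssociationMap
from .trait_processing import TraitMatrix

TRAITS = [
    "leaf_thickness_um",
    "leaf_toughness_n",
    "chlorophyll_ug_cm2",
    "sla_m2_kg",
    "wsg_g_cm3",
    "bark_thickness_mm",
    "hmax_m",
]

GUILDS = ["pioneer", "light-demanding", "shade-tolerant"]

# log-scale trait medians for the shade-tolerant baseline, and the
# log-scale shift applied at acquisitiveness score 1 (full pioneer);
# pioneers have higher SLA and thinner, softer, lighter tissues.
_TRAIT_LOG_MEDIAN = {
    "leaf_thickness_um": np.log(250.0),
    "leaf_toughness_n": np.log(1.2),
    "chlorophyll_ug_cm2": np.log(55.0),
    "sla_m2_kg": np.log(12.0),
    "wsg_g_cm3": np.log(0.70),
    "bark_thickness_mm": np.log(4.0),
    "hmax_m": np.log(35.0),
}
_TRAIT_GUILD_SHIFT = {
    "leaf_thickness_um": -0.30,
    "leaf_toughness_n": -0.60,
    "chlorophyll_ug_cm2": -0.20,
    "sla_m2_kg": 0.50,
    "wsg_g_cm3": -0.35,
    "bark_thickness_mm": -0.10,
    "hmax_m": -0.50,
}
# sign with which the species-level acquisitiveness residual loads on
# each trait: induces the within-guild SLA-WSG / SLA-toughness trade-off.
_TRAIT_AXIS_SIGN = {
    "leaf_thickness_um": -1.0,
    "leaf_toughness_n": -1.0,
    "chlorophyll_ug_cm2": -0.5,
    "sla_m2_kg": 1.0,
    "wsg_g_cm3": -1.0,
    "bark_thickness_mm": 0.0,
    "hmax_m": -0.5,
}
_GUILD_SCORE = {"pioneer": 1.0, "light-demanding": 0.5, "shade-tolerant": 0.0}
# shade-intolerant taxa are rare in a closed-canopy standing community even
# when they are speciose; their stem share is scaled down accordingly
_GUILD_BASE_FACTOR = {"pioneer": 0.25, "light-demanding": 0.6, "shade-tolerant": 1.0}

_DEFAULT_AGB = (0.0, 0.0, 0.0, 12.0, 18.0, 25.0, 30.0, 33.0, 38.0, 45.0, 50.0, 56.0)


@dataclass
class ScenarioConfig:
    """All knobs of the generator; defaults are the emulated study design.

    Rates are probabilities in [0, 1]. ``agb_lost_pct`` must list one
    value per plot, zero for controls. ``peak_time``/``peak_width`` are
    the centre (years since disturbance) and Gaussian width of the
    pioneer recruitment pulse; ``turnover_amplitude`` is the pulse peak
    mixture weight reached at the top of the gradient.
    """

    n_plots: int = 12
    plot_area_ha: float = 6.25
    agb_lost_pct: Sequence[float] = _DEFAULT_AGB
    n_species: int = 600
    guild_proportions: dict = field(
        default_factory=lambda: {"pioneer": 0.15, "light-demanding": 0.25, "shade-tolerant": 0.60}
    )
    stems_per_ha: float = 620.0
    disturbance_year: int = 1987
    horizon: int = 30
    base_recruits_per_year: float = 60.0
    recruit_slope: float = 2.0
    peak_time: float = 15.0
    peak_width: float = 8.0
    turnover_amplitude: float = 0.9
    pioneer_boost: float = 3.0
    pulse_concentration: float = 1.5
    survivor_mortality: float = 0.01
    recruit_mortality: float = 0.02
    ambiguity_rate: float = 0.5
    id_loss_rate: float = 0.3
    trait_missing_species_frac: float = 0.13
    trait_unsampled_frac: float = 0.40
    sad_log_series_x: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        self.agb_lost_pct = tuple(float(v) for v in self.agb_lost_pct)
        if len(self.agb_lost_pct) != self.n_plots:
            raise ValueError("agb_lost_pct must list one value per plot")
        if any(not (0 <= v <= 100) for v in self.agb_lost_pct):
            raise ValueError("agb_lost_pct values must lie in [0, 100]")
        for name in (
            "ambiguity_rate",
            "id_loss_rate",
            "trait_missing_species_frac",
            "trait_unsampled_frac",
            "survivor_mortality",
            "recruit_mortality",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if not (0 < self.peak_time <= self.horizon):
            raise ValueError("peak_time must lie within the horizon")
        props = self.guild_proportions
        if any(p < 0 for p in props.values()) or sum(props.values()) <= 0:
            raise ValueError("degenerate guild proportions")
        if set(props) - set(GUILDS):
            raise ValueError(f"unknown guilds {set(props) - set(GUILDS)}")

    @property
    def plot_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_plots)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["agb_lost_pct"] = list(self.agb_lost_pct)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


@dataclass
class SpeciesPool:
    """Species table: taxonomy, guild, true traits and base abundances."""

    table: pd.DataFrame  # species, genus, family, guild, base_abundance, 7 traits

    def __post_init__(self) -> None:
        total = self.table["base_abundance"].sum()
        if not np.isclose(total, 1.0):
            raise ValueError("base abundances must sum to 1")

    @property
    def species(self) -> pd.Index:
        return pd.Index(self.table["species"])

    def taxonomy(self) -> pd.DataFrame:
        return self.table.set_index("species")[["genus", "family"]]

    def true_traits(self) -> pd.DataFrame:
        return self.table.set_index("species")[TRAITS]


@dataclass
class GroundTruth:
    """Per-tree truth: species, guild, recruitment and death years."""

    trees: pd.DataFrame  # tree_id, plot_id, species, guild, recruit_year, death_year
    pool: SpeciesPool


def generate_species_pool(cfg: ScenarioConfig, rng: np.random.Generator) -> SpeciesPool:
    """Draw a species pool with log-series abundances and guild-structured traits.

    Species nest in genera and genera in families (sizes geometric-like);
    guilds are assigned at genus level with occasional within-genus
    deviation, giving the taxonomic signal that genus/family-restricted
    trait imputation exploits. Traits are drawn lognormally around
    guild-shifted medians with a shared acquisitiveness axis, so SLA is
    negatively associated with wood specific gravity and leaf toughness.
    """
    s = cfg.n_species
    # taxonomy: ~3.5 species per genus, ~4 genera per family on average
    n_genera = max(2, int(round(s / 3.5)))
    n_families = max(2, int(round(n_genera / 4.0)))
    genus_of_species = np.sort(rng.integers(0, n_genera, size=s))
    family_of_genus = np.sort(rng.integers(0, n_families, size=n_genera))

    props = np.array([cfg.guild_proportions.get(g, 0.0) for g in GUILDS], dtype=float)
    props = props / props.sum()
    genus_guild = rng.choice(len(GUILDS), size=n_genera, p=props)
    guild_idx = genus_guild[genus_of_species]
    # 10% of species deviate from their genus guild
    deviate = rng.random(s) < 0.10
    guild_idx[deviate] = rng.choice(len(GUILDS), size=int(deviate.sum()), p=props)
    guilds = np.array(GUILDS)[guild_idx]

    score = np.array([_GUILD_SCORE[g] for g in guilds])
    genus_eff = rng.normal(0.0, 0.15, size=(n_genera, len(TRAITS)))
    axis = rng.normal(0.0, 0.15, size=s)  # species acquisitiveness residual
    traits = {}
    for j, t in enumerate(TRAITS):
        log_v = (
            _TRAIT_LOG_MEDIAN[t]
            + _TRAIT_GUILD_SHIFT[t] * score
            + genus_eff[genus_of_species, j]
            + _TRAIT_AXIS_SIGN[t] * axis
            + rng.normal(0.0, 0.10, size=s)
        )
        traits[t] = np.exp(log_v)

    counts = stats.logser.rvs(cfg.sad_log_series_x, size=s, random_state=rng).astype(float)
    # standing abundance and recruitment potential are decoupled and drawn
    # independently: a closed canopy keeps shade-intolerant adults rare
    # however fecund they are, while the post-gap seed rain of a pioneer is
    # unrelated to its (near-absent) standing adult population
    standing = counts * np.array([_GUILD_BASE_FACTOR[g] for g in guilds])
    base = standing / standing.sum()
    fecundity = stats.logser.rvs(cfg.sad_log_series_x, size=s, random_state=rng).astype(float)
    recruit_w = fecundity / fecundity.sum()

    table = pd.DataFrame(
        {
            "species": [f"Genus{g:03d} sp{i:03d}" for i, g in enumerate(genus_of_species)],
            "genus": [f"Genus{g:03d}" for g in genus_of_species],
            "family": [f"Family{family_of_genus[g]:02d}" for g in genus_of_species],
            "guild": guilds,
            "base_abundance": base,
            "recruit_weight": recruit_w,
            **traits,
        }
    )
    return SpeciesPool(table)


def _pioneer_weight(cfg: ScenarioConfig, agb_lost: float, t: float) -> float:
    """Mixture weight on the pioneer/light-demanding pool at time t."""
    if agb_lost <= 0:
        return 0.0
    amp = cfg.turnover_amplitude * min(agb_lost / 60.0, 1.0)
    return amp * float(np.exp(-0.5 * ((t - cfg.peak_time) / cfg.peak_width) ** 2))


def simulate_inventory(
    pool: SpeciesPool, cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[InventoryTable, DisturbanceTable, GroundTruth]:
    """Simulate annual censuses from one year before disturbance to the horizon.

    The predisturbance standing community is a multinomial draw from base
    abundances; disturbance kills a stem fraction equal to the plot's
    fractional AGB loss; survivors then die at a small constant annual
    rate. Each subsequent year a Poisson number of recruits (mean
    increasing linearly in %AGB lost) enters at the 10 cm threshold, each
    with a sub-threshold record in the previous census so the crossing
    rule is exercised literally, and dies thereafter at a constant annual
    rate. Recruit species come from the pioneer-pulse mixture.
    """
    table = pool.table
    y0 = cfg.disturbance_year
    last_year = y0 + cfg.horizon
    base_p = table["base_abundance"].to_numpy()
    light_mask = table["guild"].isin(["pioneer", "light-demanding"]).to_numpy()
    pioneer_mask = (table["guild"] == "pioneer").to_numpy()
    # post-disturbance recruitment is dominated by few acquisitive taxa:
    # draw the pulse from recruitment potential (not standing abundance),
    # boost pioneers over light-demanders and sharpen the distribution
    recruit_w = table["recruit_weight"].to_numpy()
    light_p = np.where(light_mask, recruit_w, 0.0)
    light_p = light_p * np.where(pioneer_mask, cfg.pioneer_boost, 1.0)
    if light_p.sum() > 0:
        light_p = light_p**cfg.pulse_concentration
        light_p = light_p / light_p.sum()
    else:
        light_p = base_p

    rows_tree, rows_plot, rows_year, rows_dbh, rows_alive, rows_species = [], [], [], [], [], []
    truth_rows = []
    tid = 0

    def emit(tree_id, plot, species, years, dbhs, alive_flags):
        rows_tree.append(np.full(len(years), tree_id))
        rows_plot.append(np.full(len(years), plot))
        rows_year.append(np.asarray(years))
        rows_dbh.append(np.asarray(dbhs))
        rows_alive.append(np.asarray(alive_flags))
        rows_species.append(np.full(len(years), species))

    species_names = table["species"].to_numpy()
    guild_names = table["guild"].to_numpy()

    for plot, agb in zip(cfg.plot_ids, cfg.agb_lost_pct):
        n_init = int(round(cfg.stems_per_ha * cfg.plot_area_ha))
        sp_idx = rng.choice(len(table), size=n_init, p=base_p)
        dbh0 = 10.0 + rng.exponential(12.0, size=n_init)
        killed = rng.random(n_init) < agb / 100.0
        # background survivor death year (geometric), capped at horizon
        surv_life = rng.geometric(max(cfg.survivor_mortality, 1e-9), size=n_init)
        for i in range(n_init):
            tree_id = f"{plot}_{tid:06d}"
            tid += 1
            if killed[i]:
                death = y0
            else:
                death = min(y0 + int(surv_life[i]), last_year + 1)
            years = np.arange(y0 - 1, min(death, last_year) + 1)
            alive = years < death
            dbhs = dbh0[i] + 0.2 * (years - (y0 - 1))
            emit(tree_id, plot, species_names[sp_idx[i]], years, dbhs, alive)
            truth_rows.append(
                (tree_id, plot, species_names[sp_idx[i]], guild_names[sp_idx[i]],
                 np.nan, death if death <= last_year else np.nan)
            )
        # recruitment
        mean_recruits = cfg.base_recruits_per_year * (1.0 + cfg.recruit_slope * agb / 100.0)
        for year in range(y0 + 1, last_year + 1):
            t = year - y0
            n_rec = rng.poisson(mean_recruits)
            if n_rec == 0:
                continue
            w = _pioneer_weight(cfg, agb, t)
            from_light = rng.random(n_rec) < w
            sp_rec = np.where(
                from_light,
                rng.choice(len(table), size=n_rec, p=light_p),
                rng.choice(len(table), size=n_rec, p=base_p),
            )
            life = rng.geometric(max(cfg.recruit_mortality, 1e-9), size=n_rec)
            dbh_at_rec = 10.0 + rng.random(n_rec)
            dbh_before = 7.0 + 3.0 * rng.random(n_rec)
            for i in range(n_rec):
                tree_id = f"{plot}_{tid:06d}"
                tid += 1
                death = min(year + int(life[i]), last_year + 1)
                years = np.arange(year - 1, min(death, last_year) + 1)
                alive = years < death
                dbhs = np.concatenate(
                    [[dbh_before[i]], dbh_at_rec[i] + 0.4 * (years[1:] - year)]
                )
                emit(tree_id, plot, species_names[sp_rec[i]], years, dbhs, alive)
                truth_rows.append(
                    (tree_id, plot, species_names[sp_rec[i]], guild_names[sp_rec[i]],
                     year, death if death <= last_year else np.nan)
                )

    records = pd.DataFrame(
        {
            "tree_id": np.concatenate(rows_tree),
            "plot_id": pd.Categorical(np.concatenate(rows_plot)),
            "year": np.concatenate(rows_year).astype(np.int32),
            "dbh_cm": np.concatenate(rows_dbh).astype(np.float32),
            "vernacular": "",
            "species": np.concatenate(rows_species),
            "alive": np.concatenate(rows_alive),
        }
    )[INVENTORY_COLUMNS]
    inv = InventoryTable(records, disturbance_year=y0)
    dist = DisturbanceTable(
        pd.DataFrame(
            {
                "plot_id": cfg.plot_ids,
                "agb_lost_pct": list(cfg.agb_lost_pct),
                "treatment_label": ["control" if a == 0 else "disturbed" for a in cfg.agb_lost_pct],
            }
        )
    )
    truth = GroundTruth(
        trees=pd.DataFrame(
            truth_rows,
            columns=["tree_id", "plot_id", "species", "guild", "recruit_year", "death_year"],
        ),
        pool=pool,
    )
    return inv, dist, truth


def degrade_identifications(
    inv: InventoryTable,
    pool: SpeciesPool,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[InventoryTable, AssociationMap]:
    """Attach vernacular names and erase botanical identity for some trees.

    A configured fraction of vernacular names cover two or three species
    (grouped within families, as field names usually confound related
    taxa); a configured fraction of trees keep only the vernacular, their
    species set to the UNRESOLVED sentinel on every record. Returns the
    degraded inventory and the generating association map, whose alphas
    are the species' base abundances renormalised within each vernacular
    group.
    """
    table = pool.table
    vern_of_species: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    v = 0
    for _, fam_tbl in table.groupby("family", sort=True):
        sp = fam_tbl["species"].tolist()
        order = rng.permutation(len(sp))
        i = 0
        while i < len(sp):
            if rng.random() < cfg.ambiguity_rate and len(sp) - i >= 2:
                size = 2 if (rng.random() < 0.6 or len(sp) - i < 3) else 3
            else:
                size = 1
            name = f"vern_{v:04d}"
            v += 1
            members = [sp[order[k]] for k in range(i, i + size)]
            groups[name] = members
            for m in members:
                vern_of_species[m] = name
            i += size

    abund = table.set_index("species")["base_abundance"]
    mapping = {}
    for name, members in groups.items():
        a = abund.loc[members].to_numpy()
        mapping[name] = list(zip(members, a / a.sum()))
    assoc = AssociationMap(mapping)

    rec = inv.records.copy()
    rec["vernacular"] = rec["species"].map(vern_of_species).fillna("")
    trees = rec["tree_id"].unique()
    lost = pd.Index(trees[rng.random(len(trees)) < cfg.id_loss_rate])
    rec.loc[rec["tree_id"].isin(lost), "species"] = UNRESOLVED
    return InventoryTable(rec, inv.disturbance_year, inv.census_interval), assoc


def degrade_traits(
    pool: SpeciesPool, cfg: ScenarioConfig, rng: np.random.Generator
) -> TraitMatrix:
    """Build the observed trait table: dropped species and masked cells.

    A fraction of species is absent from the trait campaign entirely; of
    the sampled species, a fraction has one to three trait values masked
    at random. Taxonomy covers all species (sampled or not) so donor
    lookups work downstream; ground truth stays in the pool.
    """
    table = pool.table
    n = len(table)
    n_drop = int(round(cfg.trait_unsampled_frac * n))
    if n_drop >= n:
        raise ValueError("all species dropped from the trait campaign")
    dropped = rng.choice(n, size=n_drop, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[dropped] = False
    traits = pool.true_traits().loc[table.loc[keep, "species"]].copy()
    sampled = traits.index.to_numpy()
    n_miss = int(round(cfg.trait_missing_species_frac * len(sampled)))
    with_missing = rng.choice(sampled, size=n_miss, replace=False)
    for sp in with_missing:
        k = int(rng.integers(1, 4))
        cols = rng.choice(len(TRAITS), size=k, replace=False)
        traits.loc[sp, [TRAITS[c] for c in cols]] = np.nan
    return TraitMatrix(traits=traits, taxonomy=pool.taxonomy())
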