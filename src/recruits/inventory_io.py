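"""Forest-inventory tables: reading, writing, cohort and community extraction.

The central object is the :class:`InventoryTable`: one row per tree per
census year, with columns ``tree_id, plot_id, year, dbh_cm, vernacular,
species, alive``. Trees are inventoried from 10 cm diameter at breast
height (DBH) upward; a tree whose species is not botanically determined
carries the sentinel ``"UNRESOLVED"`` in the species column and (usually)
a vernacular field name.

Recruitment is defined by threshold crossing: for an observation time T
(years since disturbance), the recruit cohort holds the trees that were
below the DBH threshold one census interval before T (or absent, never
having reached the threshold) and at or above it at T. Trees already at
or above the threshold at the last predisturbance census ("survivors")
belong to no cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNRESOLVED = "UNRESOLVED"

INVENTORY_COLUMNS = ["tree_id", "plot_id", "year", "dbh_cm", "vernacular", "species", "alive"]


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class CensusGapError(ValueError):
    """A census year is missing inside the analysis window."""


@dataclass
class InventoryTable:
    """Longitudinal tree records plus the disturbance calendar.

    ``records`` has the canonical columns; ``disturbance_year`` anchors
    the "years since disturbance" time axis for every plot;
    ``census_interval`` is the spacing of censuses in years (annual by
    default).
    """

    records: pd.DataFrame
    disturbance_year: int
    census_interval: int = 1

    def __post_init__(self) -> None:
        missing = [c for c in INVENTORY_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"inventory records missing columns: {missing}")
        dup = self.records.duplicated(subset=["tree_id", "year"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (tree_id, year) pairs in inventory"
            )

    @property
    def plots(self) -> list:
        return sorted(self.records["plot_id"].unique())

    def census_years(self, plot_id=None) -> np.ndarray:
        rec = self.records
        if plot_id is not None:
            rec = rec[rec["plot_id"] == plot_id]
        return np.sort(rec["year"].unique())


@dataclass
class DisturbanceTable:
    """Per-plot disturbance intensity: percent aboveground biomass lost."""

    table: pd.DataFrame  # columns: plot_id, agb_lost_pct, treatment_label

    def __post_init__(self) -> None:
        missing = [c for c in ("plot_id", "agb_lost_pct") if c not in self.table.columns]
        if missing:
            raise SchemaError(f"disturbance table missing columns: {missing}")
        pct = self.table["agb_lost_pct"]
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("agb_lost_pct must lie in [0, 100]")
        if "treatment_label" not in self.table.columns:
            self.table = self.table.assign(treatment_label="")

    def agb_lost(self, plot_id) -> float:
        row = self.table.loc[self.table["plot_id"] == plot_id, "agb_lost_pct"]
        if row.empty:
            raise KeyError(f"plot {plot_id!r} absent from disturbance table")
        return float(row.iloc[0])


@dataclass
class CohortAbundance:
    """Species abundance vector for one plot at one observation time.

    ``time`` is in years since disturbance; the predisturbance community
    uses ``time = -1`` (the census preceding disturbance). ``counts``
    maps resolved species names to positive integers.
    """

    plot_id: str
    time: int
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


# ---------------------------------------------------------------------------
# I/O


def read_inventory(
    path,
    disturbance_year: int,
    schema: Mapping[str, str] | None = None,
    census_interval: int = 1,
) -> InventoryTable:
    """Read an inventory CSV, validate rows, and report rejections.

    ``schema`` maps canonical column names to the file's column names
    (identity by default). Rows with nonpositive DBH are rejected and
    counted in the log; a missing required column raises
    :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"species": str, "vernacular": str})
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in INVENTORY_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SchemaError(f"input file {path} lacks required columns: {missing}")
    df = df.rename(columns=rename)[INVENTORY_COLUMNS]
    df["vernacular"] = df["vernacular"].fillna("")
    df["species"] = df["species"].fillna(UNRESOLVED)
    df["alive"] = df["alive"].astype(bool)
    bad = df["dbh_cm"] <= 0
    if bad.any():
        logger.warning("rejected %d rows with nonpositive DBH from %s", int(bad.sum()), path)
        df = df[~bad].reset_index(drop=True)
    return InventoryTable(df, disturbance_year=disturbance_year, census_interval=census_interval)


def write_inventory(inv: InventoryTable, path) -> None:
    inv.records[INVENTORY_COLUMNS].to_csv(path, index=False)


def read_disturbance(path) -> DisturbanceTable:
    return DisturbanceTable(pd.read_csv(path))


def write_disturbance(dist: DisturbanceTable, path) -> None:
    dist.table.to_csv(path, index=False)


def write_cohorts(cohorts: Sequence[CohortAbundance], path) -> None:
    rows = [
        {"plot_id": c.plot_id, "time": c.time, "species": s, "count": n}
        for c in cohorts
        for s, n in sorted(c.counts.items())
    ]
    pd.DataFrame(rows, columns=["plot_id", "time", "species", "count"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort and community extraction


def _check_census_coverage(inv: InventoryTable, horizon: int) -> None:
    expected = np.arange(
        inv.disturbance_year - 1, inv.disturbance_year + horizon + 1, inv.census_interval
    )
    for plot in inv.plots:
        got = set(inv.census_years(plot))
        gaps = [int(y) for y in expected if y not in got]
        if gaps:
            raise CensusGapError(f"plot {plot!r}: missing census years {gaps}")


def _first_crossing_years(records: pd.DataFrame, dbh_threshold: float) -> pd.Series:
    """Year each tree first reached the DBH threshold while alive."""
    above = records[(records["dbh_cm"] >= dbh_threshold) & records["alive"]]
    return above.groupby("tree_id", sort=False)["year"].min()


def survivor_ids(inv: InventoryTable, dbh_threshold: float = 10.0) -> pd.Index:
    """Trees at or above the threshold at the last census before disturbance."""
    rec = inv.records
    pre_years = rec.loc[rec["year"] < inv.disturbance_year, "year"]
    if pre_years.empty:
        raise ValueError("no census at or before the disturbance year")
    pre = rec[
        (rec["year"] == pre_years.max())
        & (rec["dbh_cm"] >= dbh_threshold)
        & rec["alive"]
    ]
    return pd.Index(pre["tree_id"].unique())


def observation_times(start_offset: int = 5, interval: int = 2, horizon: int = 30) -> np.ndarray:
    """Observation grid in years since disturbance: start, start+interval, ... <= horizon."""
    return np.arange(start_offset, horizon + 1, interval)


def cohort_members(
    inv: InventoryTable,
    interval: int = 2,
    start_offset: int = 5,
    horizon: int = 30,
    dbh_threshold: float = 10.0,
) -> pd.DataFrame:
    """Tree-id membership of every recruit cohort, independent of species.

    Returns a DataFrame with columns ``plot_id, time, tree_id`` listing,
    for each plot and each observation time T on the grid, the trees
    recruited in (T - interval, T]: alive and at/above the threshold at
    T, with their first threshold crossing inside the window. Survivors
    of the disturbance are excluded. Because membership depends only on
    DBH and years, it is computed once and reused across taxonomic
    resolutions.
    """
    _check_census_coverage(inv, horizon)
    rec = inv.records
    surv = set(survivor_ids(inv, dbh_threshold))
    first_cross = _first_crossing_years(rec, dbh_threshold)
    first_cross = first_cross[~first_cross.index.isin(surv)]

    # trees alive and above threshold per census year
    alive_above = rec[(rec["dbh_cm"] >= dbh_threshold) & rec["alive"]]
    out = []
    for t in observation_times(start_offset, interval, horizon):
        year = inv.disturbance_year + int(t)
        at_t = alive_above[alive_above["year"] == year]
        fc = first_cross.reindex(at_t["tree_id"])
        in_window = (fc.to_numpy() > year - interval) & (fc.to_numpy() <= year)
        sel = at_t.loc[in_window.astype(bool)]
        for plot, tree in zip(sel["plot_id"], sel["tree_id"]):
            out.append((plot, int(t), tree))
    return pd.DataFrame(out, columns=["plot_id", "time", "tree_id"])


def tree_species(inv: InventoryTable) -> pd.Series:
    """Per-tree species label (must be constant across a tree's records)."""
    sp = inv.records.groupby("tree_id", sort=False)["species"].agg(["first", "nunique"])
    if (sp["nunique"] > 1).any():
        bad = sp.index[sp["nunique"] > 1].tolist()[:5]
        raise ValueError(f"trees with inconsistent species labels, e.g. {bad}")
    return sp["first"]


def extract_recruit_cohorts(
    inv: InventoryTable,
    dist: DisturbanceTable,
    interval: int = 2,
    start_offset: int = 5,
    horizon: int = 30,
    dbh_threshold: float = 10.0,
) -> list[CohortAbundance]:
    """Species abundance of every 2-year recruit cohort, per plot and time.

    The inventory must be fully resolved (no ``UNRESOLVED`` species);
    resolve taxonomic uncertainty first. Control plots share the
    calendar start of disturbed plots because the time axis is anchored
    at the common disturbance year. Cohorts with zero recruits are not
    emitted.
    """
    unknown = set(inv.records["plot_id"].unique()) - set(dist.table["plot_id"])
    if unknown:
        raise KeyError(f"plots absent from disturbance table: {sorted(unknown)}")
    members = cohort_members(inv, interval, start_offset, horizon, dbh_threshold)
    species = tree_species(inv)
    if (species == UNRESOLVED).any():
        n = int((species == UNRESOLVED).sum())
        raise ValueError(f"{n} trees unresolved; run taxonomy resolution before cohorts")
    return cohorts_from_members(members, species)


def cohorts_from_members(members: pd.DataFrame, species: pd.Series) -> list[CohortAbundance]:
    """Assemble cohort abundance vectors from membership and a species map."""
    out = []
    sp = members.assign(species=species.reindex(members["tree_id"]).to_numpy())
    for (plot, t), grp in sp.groupby(["plot_id", "time"], sort=True):
        counts = grp["species"].value_counts().to_dict()
        out.append(CohortAbundance(plot_id=plot, time=int(t), counts=counts))
    return out


def predisturbance_community(inv: InventoryTable, dbh_threshold: float = 10.0) -> dict:
    """Whole predisturbance community per plot: all trees >= threshold
    at the last census before (or at) disturbance, survivors included.
    """
    rec = inv.records
    pre_years = rec.loc[rec["year"] < inv.disturbance_year, "year"]
    if pre_years.empty:
        raise ValueError("no census at or before the disturbance year")
    year = pre_years.max()
    pre = rec[(rec["year"] == year) & (rec["dbh_cm"] >= dbh_threshold) & rec["alive"]]
    out = {}
    for plot in inv.plots:
        sub = pre[pre["plot_id"] == plot]
        if sub.empty:
            raise ValueError(f"plot {plot!r}: empty predisturbance community")
        if (sub["species"] == UNRESOLVED).any():
            raise ValueError(f"plot {plot!r}: unresolved species in predisturbance census")
        out[plot] = CohortAbundance(
            plot_id=plot, time=-1, counts=sub["species"].value_counts().to_dict()
        )
    return out


def standing_community_members(inv: InventoryTable, dbh_threshold: float = 10.0) -> pd.DataFrame:
    """Tree ids of all living trees >= threshold per (plot, census year).

    This is the candidate pool ("the community of the year and plot")
    that taxonomic null models resample from.
    """
    rec = inv.records
    alive_above = rec[(rec["dbh_cm"] >= dbh_threshold) & rec["alive"]]
    return alive_above[["plot_id", "year", "tree_id"]].reset_index(drop=True)
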