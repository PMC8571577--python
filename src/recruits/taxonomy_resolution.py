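"""Taxonomic-uncertainty estimation and propagation.

Field crews attribute vernacular names; botanists later resolve a subset
of trees to species. A vernacular name v therefore maps to a probability
vector over botanical species — the association probabilities
[alpha_1, ..., alpha_N] observed across all inventories. Unresolved
trees are completed by multinomial trials from their vernacular's
categorical distribution, once per tree (a tree cannot change species
between censuses). Repeating the resolution many times and recomputing
any downstream metric yields an ensemble whose percentile band is the
taxonomic-uncertainty confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .inventory_io import UNRESOLVED, InventoryTable

logger = logging.getLogger(__name__)


class UnresolvableVernacularError(ValueError):
    """Vernacular names with no association and fallback disabled."""

    def __init__(self, names: Iterable[str]):
        self.names = sorted(names)
        super().__init__(f"unresolvable vernacular names: {self.names}")


@dataclass
class AssociationMap:
    """vernacular -> [(species, alpha), ...] with alphas summing to one."""

    mapping: dict

    def __post_init__(self) -> None:
        for v, pairs in self.mapping.items():
            species = [s for s, _ in pairs]
            if len(set(species)) != len(species):
                raise ValueError(f"duplicate species under vernacular {v!r}")
            alphas = np.array([a for _, a in pairs], dtype=float)
            if (alphas <= 0).any() or abs(alphas.sum() - 1.0) > 1e-9:
                raise ValueError(f"alphas for vernacular {v!r} must be positive and sum to 1")

    def species_of(self, vernacular: str) -> list[str]:
        return [s for s, _ in self.mapping[vernacular]]

    def alphas_of(self, vernacular: str) -> np.ndarray:
        return np.array([a for _, a in self.mapping[vernacular]], dtype=float)

    @property
    def all_species(self) -> list[str]:
        return sorted({s for pairs in self.mapping.values() for s, _ in pairs})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"vernacular": v, "species": s, "alpha": a}
            for v, pairs in sorted(self.mapping.items())
            for s, a in pairs
        ]
        return pd.DataFrame(rows, columns=["vernacular", "species", "alpha"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssociationMap":
        mapping = {
            v: list(zip(grp["species"], grp["alpha"]))
            for v, grp in df.groupby("vernacular", sort=True)
        }
        return cls(mapping)

    @classmethod
    def from_csv(cls, path) -> "AssociationMap":
        return cls.from_frame(pd.read_csv(path))


def estimate_association_probabilities(inv: InventoryTable) -> AssociationMap:
    """Estimate alphas by pooled co-occurrence counting.

    alpha(v, s) is the number of records carrying vernacular v together
    with resolved species s, divided by the number of resolved records
    with vernacular v, pooled over all plots and censuses. Vernaculars
    that never co-occur with a resolved species are absent from the map
    (and logged); resolution handles them via its fallback.
    """
    rec = inv.records
    resolved = rec[(rec["vernacular"] != "") & (rec["species"] != UNRESOLVED)]
    if resolved.empty:
        raise ValueError("no record carries both a vernacular and a resolved species")
    counts = resolved.groupby(["vernacular", "species"], observed=True).size()
    mapping: dict[str, list] = {}
    for v, grp in counts.groupby(level=0, observed=True):
        total = grp.sum()
        mapping[str(v)] = [(str(s), c / total) for (_, s), c in grp.items()]
    seen = set(rec.loc[rec["vernacular"] != "", "vernacular"].unique())
    uncovered = seen - set(mapping)
    if uncovered:
        logger.warning(
            "%d vernacular names never co-occur with a resolved species: %s",
            len(uncovered), sorted(uncovered)[:10],
        )
    return AssociationMap(mapping)


def resolve_inventory(
    inv: InventoryTable,
    assoc: AssociationMap,
    rng: np.random.Generator,
    fallback: bool = True,
    taxonomy: pd.DataFrame | None = None,
) -> InventoryTable:
    """Fill every UNRESOLVED species by one multinomial trial per tree.

    The draw is made once per tree and applied to all its census records.
    Resolved trees are untouched; record counts, tree ids, DBH values and
    plot assignments are preserved exactly.

    Vernaculars absent from the association map fall back (if enabled) to
    a uniform draw over species of the map sharing the vernacular's most
    frequent family when a taxonomy is supplied, else over all species in
    the map; fallback use is logged. With ``fallback=False`` such names
    raise :class:`UnresolvableVernacularError`.
    """
    rec = inv.records
    unresolved_mask = rec["species"] == UNRESOLVED
    if not unresolved_mask.any():
        return inv

    trees = rec.loc[unresolved_mask, ["tree_id", "vernacular"]].drop_duplicates("tree_id")
    missing = set(trees["vernacular"].unique()) - set(assoc.mapping)
    if missing and not fallback:
        raise UnresolvableVernacularError(missing)
    if missing:
        logger.warning("fallback resolution used for vernaculars: %s", sorted(missing)[:10])

    pool = assoc.all_species
    fallback_species: dict[str, list[str]] = {}
    for v in missing:
        choices = pool
        if taxonomy is not None and "family" in taxonomy.columns:
            fams = taxonomy.reindex(pool)["family"].dropna()
            if not fams.empty:
                top = fams.mode().iloc[0]
                fam_pool = fams.index[fams == top].tolist()
                choices = fam_pool or pool
        fallback_species[v] = list(choices)

    draws = {}
    for tree_id, v in zip(trees["tree_id"], trees["vernacular"]):
        if v in assoc.mapping:
            species = assoc.species_of(v)
            alphas = assoc.alphas_of(v)
            draws[tree_id] = species[rng.choice(len(species), p=alphas)]
        else:
            choices = fallback_species[v]
            draws[tree_id] = choices[rng.integers(len(choices))]

    out = rec.copy()
    resolved_col = out.loc[unresolved_mask, "tree_id"].map(draws)
    out.loc[unresolved_mask, "species"] = resolved_col
    return InventoryTable(out, inv.disturbance_year, inv.census_interval)


@dataclass
class MetricEnsemble:
    """iteration x time matrix of one metric's values under resolution draws."""

    values: np.ndarray  # shape (n_iter, n_times)
    times: np.ndarray
    metric: str
    plot_id: str | None = None

    @property
    def n_iter(self) -> int:
        return self.values.shape[0]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        lo = (1.0 - level) / 2.0 * 100.0
        return (
            np.percentile(self.values, lo, axis=0),
            np.percentile(self.values, 100.0 - lo, axis=0),
        )


def propagate(
    inv: InventoryTable,
    assoc: AssociationMap,
    metric_fn: Callable[[InventoryTable], np.ndarray],
    times: np.ndarray,
    n_iter: int = 100,
    rng: np.random.Generator | None = None,
    metric_name: str = "metric",
    **resolve_kwargs,
) -> tuple[MetricEnsemble, pd.DataFrame]:
    """Propagate taxonomic uncertainty through a metric pipeline.

    ``metric_fn`` must be deterministic given a resolved inventory and
    return one value per entry of ``times``. Each of the ``n_iter``
    iterations resolves the inventory with an independent child RNG
    stream, then applies the metric. Returns the ensemble and a frame
    with per-time mean and percentile 95% confidence bounds.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2 to form a confidence interval")
    rng = np.random.default_rng() if rng is None else rng
    streams = rng.spawn(n_iter)
    values = np.empty((n_iter, len(times)))
    for i, stream in enumerate(streams):
        resolved = resolve_inventory(inv, assoc, stream, **resolve_kwargs)
        vals = np.asarray(metric_fn(resolved), dtype=float)
        if vals.shape != (len(times),):
            raise ValueError("metric_fn must return one value per time point")
        values[i] = vals
    ens = MetricEnsemble(values=values, times=np.asarray(times), metric=metric_name)
    lo, hi = ens.ci()
    frame = pd.DataFrame(
        {"time": np.asarray(times), "value": ens.mean(), "ci_low": lo, "ci_high": hi}
    )
    return ens, frame
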