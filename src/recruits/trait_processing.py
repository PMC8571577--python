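"""Species x trait matrix completion, standardization, and functional distances.

Two distinct gaps arise in a trait campaign. Sampled species may miss
some traits: these cells are filled by chained-equation imputation with
predictive-mean matching, where each species' donor pool is restricted
taxonomically (congeners if enough exist, else confamilials, else the
whole table) to exploit the phylogenetic signal of traits. Species never
sampled at all receive the complete 7-trait vector of one donor drawn
uniformly from their genus (else family, else anywhere), copied jointly
so trait syndromes are preserved; this draw is meant to be repeated per
uncertainty-propagation iteration.

Functional distances are Euclidean on z-scored traits: traits come in
incommensurable units (um, N, g/cm3, m), so each is centred and scaled
to unit variance across species before the pairwise distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class TraitMatrix:
    """Species x trait values (possibly missing) plus a species taxonomy.

    ``traits`` is indexed by species; ``taxonomy`` (species -> genus,
    family) may cover more species than ``traits`` — the extra species
    are the ones absent from the trait campaign.
    """

    traits: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"genus", "family"} <= set(self.taxonomy.columns):
            raise ValueError("taxonomy must have genus and family columns")

    @property
    def species(self) -> pd.Index:
        return self.traits.index

    @property
    def complete(self) -> bool:
        return not self.traits.isna().any().any()


def _donor_rows(sp: str, trait: str, traits: pd.DataFrame, taxonomy: pd.DataFrame,
                min_congeners: int = 3) -> pd.Index:
    """Taxonomically closest donor set with the trait observed."""
    observed = traits.index[traits[trait].notna()]
    if sp in taxonomy.index:
        genus, family = taxonomy.loc[sp, "genus"], taxonomy.loc[sp, "family"]
        congeners = observed[(taxonomy.reindex(observed)["genus"] == genus) & (observed != sp)]
        if len(congeners) >= min_congeners:
            return congeners
        confam = observed[(taxonomy.reindex(observed)["family"] == family) & (observed != sp)]
        if len(confam) >= min_congeners:
            return confam
    return observed[observed != sp]


def impute_missing_traits(
    tm: TraitMatrix,
    rng: np.random.Generator,
    n_sweeps: int = 5,
    pmm_k: int = 5,
    min_congeners: int = 3,
) -> TraitMatrix:
    """Fill missing cells by chained equations with taxonomic donor pools.

    Each missing cell is initialised with its donor pool's median, then
    refined over ``n_sweeps`` passes: for every trait with gaps, a linear
    regression of that trait on the other traits is fitted over species
    with the trait observed, the missing value is predicted, and the
    imputed value is drawn among the ``pmm_k`` donor-pool values closest
    to the prediction (predictive-mean matching). Imputed values
    therefore always lie within the donor pool's observed range, and
    observed cells are never altered.
    """
    traits = tm.traits.copy()
    cols = list(traits.columns)
    never = [c for c in cols if traits[c].notna().sum() == 0]
    if never:
        raise ValueError(f"traits observed for no species: {never}")
    for c in cols:
        if traits[c].notna().sum() < 2:
            raise ValueError(f"trait {c!r} observed for fewer than 2 species")
    mask = traits.isna()
    if not mask.any().any():
        return tm

    cells = [(sp, c) for c in cols for sp in traits.index[mask[c]]]
    donors = {
        (sp, c): _donor_rows(sp, c, tm.traits, tm.taxonomy, min_congeners)
        for sp, c in cells
    }
    for (sp, c), pool in donors.items():
        traits.loc[sp, c] = tm.traits.loc[pool, c].median()

    for _ in range(n_sweeps):
        for c in cols:
            gaps = [sp for sp, cc in cells if cc == c]
            if not gaps:
                continue
            others = [o for o in cols if o != c]
            obs = tm.traits.index[tm.traits[c].notna()]
            X = traits.loc[obs, others].to_numpy(dtype=float)
            y = tm.traits.loc[obs, c].to_numpy(dtype=float)
            A = np.column_stack([np.ones(len(obs)), X])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            for sp in gaps:
                x = traits.loc[sp, others].to_numpy(dtype=float)
                pred = beta[0] + x @ beta[1:]
                pool_vals = tm.traits.loc[donors[(sp, c)], c].to_numpy(dtype=float)
                k = min(pmm_k, len(pool_vals))
                nearest = pool_vals[np.argsort(np.abs(pool_vals - pred))[:k]]
                traits.loc[sp, c] = nearest[rng.integers(k)]
    return TraitMatrix(traits=traits, taxonomy=tm.taxonomy)


def assign_unsampled_species(
    species_list,
    tm: TraitMatrix,
    taxonomy: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> TraitMatrix:
    """Give every unsampled species the full trait vector of one donor.

    The donor is drawn uniformly among sampled congeners if any exist,
    else sampled confamilials, else (logged) among all sampled species.
    The 7-vector is copied jointly, preserving trait syndromes. Sampled
    species pass through unchanged. Intended to be redrawn inside each
    uncertainty-propagation iteration so assignment uncertainty reaches
    the confidence intervals.
    """
    if not tm.complete:
        raise ValueError("complete the sampled-species matrix before assignment")
    taxonomy = tm.taxonomy if taxonomy is None else taxonomy
    rng = np.random.default_rng() if rng is None else rng
    sampled = tm.traits.index
    todo = [sp for sp in species_list if sp not in sampled]
    if not todo:
        return tm
    new_rows = {}
    n_fallback = 0
    for sp in todo:
        donor_pool = pd.Index([])
        if sp in taxonomy.index:
            genus, family = taxonomy.loc[sp, "genus"], taxonomy.loc[sp, "family"]
            donor_pool = sampled[taxonomy.reindex(sampled)["genus"] == genus]
            if donor_pool.empty:
                donor_pool = sampled[taxonomy.reindex(sampled)["family"] == family]
        if donor_pool.empty:
            donor_pool = sampled
            n_fallback += 1
        donor = donor_pool[rng.integers(len(donor_pool))]
        new_rows[sp] = tm.traits.loc[donor]
    if n_fallback:
        logger.warning("%d species assigned from the full table (no congener/confamilial)",
                       n_fallback)
    out = pd.concat([tm.traits, pd.DataFrame(new_rows).T])
    out.index.name = tm.traits.index.name
    taxo = tm.taxonomy
    return TraitMatrix(traits=out, taxonomy=taxo)


def read_traits(path) -> TraitMatrix:
    """Read a trait CSV: species, genus, family, then one column per trait.

    Empty cells are missing values. Taxonomy rows with no measured trait
    at all still contribute to the taxonomy (they are the unsampled
    species); their trait rows are dropped from the matrix.
    """
    df = pd.read_csv(path).set_index("species")
    taxonomy = df[["genus", "family"]]
    traits = df.drop(columns=["genus", "family"])
    sampled = traits.notna().any(axis=1)
    return TraitMatrix(traits=traits[sampled], taxonomy=taxonomy)


def write_traits(tm: TraitMatrix, path) -> None:
    out = tm.taxonomy.join(tm.traits, how="left")
    out.index.name = "species"
    out.to_csv(path)


def standardize_and_distance(tm: TraitMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score traits across species and return (standardized, distances).

    Distances are Euclidean on the standardized vectors, so the matrix is
    symmetric with zero diagonal and satisfies the triangle inequality.
    A zero-variance trait carries no information after centring and is
    dropped with a warning.
    """
    if not tm.complete:
        raise ValueError("trait matrix must be complete")
    if len(tm.traits) < 2:
        raise ValueError("need at least two species")
    traits = tm.traits.astype(float)
    std = traits.std(ddof=0)
    dead = std.index[std == 0.0]
    if len(dead):
        logger.warning("dropping zero-variance traits from the distance: %s", list(dead))
        traits = traits.drop(columns=dead)
        std = std.drop(dead)
    z = (traits - traits.mean()) / std
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    dist = pd.DataFrame(d, index=z.index, columns=z.index)
    return z, dist
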