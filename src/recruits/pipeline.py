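"""End-to-end pipeline: simulate -> resolve -> traits -> cohorts -> metrics
-> null models -> breakpoints -> gradient correlations.

One master seed drives everything through spawned child streams, so a
rerun with the same configuration is bit-identical. Taxonomic
uncertainty and the null models share a flat iteration budget (100 by
default): each iteration re-resolves the inventory, redraws the
unsampled-species trait assignment, computes every observed metric, and
performs one taxonomic and one functional null draw, so identification,
trait-assignment and null-sampling uncertainty all reach the reported
bands.

Cohort membership and community pools depend only on DBH and census
years, never on species identity, so they are extracted once and reused
across iterations; each iteration then only redraws species labels and
recounts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inventory_io import (
    UNRESOLVED,
    DisturbanceTable,
    cohort_members,
    observation_times,
    read_disturbance,
    read_inventory,
    standing_community_members,
)
from .metrics import hill_diversity, turnover
from .null_models import taxonomic_null_draw
from .synthetic_forest import (
    TRAITS,
    ScenarioConfig,
    degrade_identifications,
    degrade_traits,
    generate_species_pool,
    simulate_inventory,
)
from .taxonomy_resolution import AssociationMap, estimate_association_probabilities
from .trait_processing import (
    assign_unsampled_species,
    impute_missing_traits,
    read_traits,
    standardize_and_distance,
)
from .trajectory_analysis import (
    TrajectorySeries,
    detect_breakpoints,
    fit_smooth_trajectory,
    max_deviation,
    spearman_test,
)

logger = logging.getLogger(__name__)

RESULT_FILES = [
    "association.csv",
    "cohorts.csv",
    "diversity_trajectories.csv",
    "turnover.csv",
    "cwm_trajectories.csv",
    "null_bands.csv",
    "breakpoints.csv",
    "correlations.csv",
]


@dataclass
class RunConfig:
    """Protocol constants and paths for one pipeline run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    inventory_path: str | None = None
    disturbance_path: str | None = None
    trait_path: str | None = None
    disturbance_year: int | None = None
    interval: int = 2
    start_offset: int = 5
    horizon: int = 30
    dbh_threshold: float = 10.0
    n_iter: int = 100
    max_breaks: int = 2
    min_seg: int = 3
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if min(self.interval, self.start_offset, self.horizon) <= 0:
            raise ValueError("durations must be positive")
        if self.horizon < self.start_offset:
            raise ValueError("horizon must be >= start_offset")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = ScenarioConfig.from_dict(raw.pop("scenario", {}) or {})
        return cls(scenario=scenario, **raw)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output."""

    diversity: pd.DataFrame
    turnover: pd.DataFrame
    cwm: pd.DataFrame
    null_bands: pd.DataFrame
    breakpoints: pd.DataFrame
    correlations: pd.DataFrame
    cohort_sizes: pd.DataFrame
    association: AssociationMap
    disturbance: DisturbanceTable
    manifest: dict


def _group_indices(df: pd.DataFrame, keys, tree_pos: np.ndarray) -> dict:
    """Map group key -> integer positions (into the unique-tree table)."""
    out = {}
    for key, grp in df.groupby(keys, observed=True, sort=True):
        out[key] = tree_pos[grp.index.to_numpy()]
    return out


def _counts(species: np.ndarray, idx: np.ndarray) -> dict[str, int]:
    vals, cnt = np.unique(species[idx], return_counts=True)
    return dict(zip(vals.tolist(), cnt.tolist()))


def run_pipeline(cfg: RunConfig, out_dir=None) -> PipelineResult:
    """Run every stage and (optionally) write the result files.

    Returns the full result bundle; when ``out_dir`` (or
    ``cfg.out_dir``) is set, the eight result CSVs and a JSON manifest
    are written there.
    """
    t_start = time.time()
    master = np.random.default_rng(cfg.seed)
    (rng_pool, rng_inv, rng_ids, rng_traits, rng_impute, rng_iter) = master.spawn(6)

    manifest: dict = {"seed": cfg.seed, "version": __version__, "stages": {}}

    if cfg.inventory_path:
        if cfg.disturbance_year is None or cfg.disturbance_path is None or cfg.trait_path is None:
            raise ValueError(
                "inventory input needs disturbance_path, trait_path and disturbance_year"
            )
        inv = read_inventory(cfg.inventory_path, disturbance_year=cfg.disturbance_year)
        dist = read_disturbance(cfg.disturbance_path)
        trait_obs = read_traits(cfg.trait_path)
        taxonomy = trait_obs.taxonomy
        manifest["stages"]["read"] = {
            "n_records": int(len(inv.records)),
            "n_trees": int(inv.records["tree_id"].nunique()),
        }
    else:
        pool = generate_species_pool(cfg.scenario, rng_pool)
        inv_true, dist, truth = simulate_inventory(pool, cfg.scenario, rng_inv)
        inv, true_assoc = degrade_identifications(inv_true, pool, cfg.scenario, rng_ids)
        trait_obs = degrade_traits(pool, cfg.scenario, rng_traits)
        taxonomy = pool.taxonomy()
        manifest["stages"]["simulate"] = {
            "n_records": int(len(inv.records)),
            "n_trees": int(inv.records["tree_id"].nunique()),
            "n_species_pool": int(cfg.scenario.n_species),
        }

    assoc = estimate_association_probabilities(inv)
    manifest["stages"]["association"] = {"n_vernaculars": len(assoc.mapping)}

    # --- species-independent structure, computed once -----------------------
    times = observation_times(cfg.start_offset, cfg.interval, cfg.horizon)
    members = cohort_members(inv, cfg.interval, cfg.start_offset, cfg.horizon, cfg.dbh_threshold)
    standing = standing_community_members(inv, cfg.dbh_threshold)
    standing = standing[
        standing["year"].isin(inv.disturbance_year + times)
    ].reset_index(drop=True)
    rec = inv.records
    pre_year = rec.loc[rec["year"] < inv.disturbance_year, "year"].max()
    pre = rec[
        (rec["year"] == pre_year) & (rec["dbh_cm"] >= cfg.dbh_threshold) & rec["alive"]
    ][["plot_id", "tree_id"]].reset_index(drop=True)

    trees = rec[["tree_id", "vernacular", "species"]].drop_duplicates("tree_id").reset_index(
        drop=True
    )
    tree_index = pd.Series(np.arange(len(trees)), index=trees["tree_id"])
    base_species = trees["species"].to_numpy(dtype=object)
    unresolved = base_species == UNRESOLVED
    vern_groups: dict[str, np.ndarray] = {}
    for v, grp in trees.loc[unresolved].groupby("vernacular"):
        vern_groups[str(v)] = grp.index.to_numpy()

    cohort_idx = _group_indices(members, ["plot_id", "time"], tree_index[members["tree_id"]].to_numpy())
    standing["time"] = standing["year"] - inv.disturbance_year
    standing_idx = _group_indices(
        standing, ["plot_id", "time"], tree_index[standing["tree_id"]].to_numpy()
    )
    pre_idx = _group_indices(pre.assign(k=0), ["plot_id"], tree_index[pre["tree_id"]].to_numpy())
    plots = [str(p) for p in dist.table["plot_id"]]
    agb = {str(p): float(a) for p, a in zip(dist.table["plot_id"], dist.table["agb_lost_pct"])}

    manifest["stages"]["cohorts"] = {
        "n_cohort_trees": int(len(members)),
        "times": [int(x) for x in times],
    }

    # --- trait completion for sampled species (imputation, once) ------------
    tm_sampled = impute_missing_traits(trait_obs, rng_impute) if trait_obs is not None else None
    all_species = sorted(set(base_species[~unresolved]) | set(assoc.all_species))

    # --- iteration loop ------------------------------------------------------
    n_iter, n_t = cfg.n_iter, len(times)
    shape = (n_iter, n_t)
    obs = {
        m: {p: np.zeros(n_t) for p in plots}
        for m in ("richness", "evenness", "rao", "turnover")
    }
    store = {m: {p: np.empty(shape) for p in plots} for m in obs}
    cwm_store = {tr: {p: np.empty(shape) for p in plots} for tr in TRAITS}
    diff_tax = {m: {p: np.empty(shape) for p in plots} for m in ("richness", "evenness")}
    diff_fun = {p: np.empty(shape) for p in plots}
    n_species_recruited = np.empty(n_iter)

    resolve_alphas = {
        v: (np.array([s for s, _ in pairs], dtype=object), np.array([a for _, a in pairs]))
        for v, pairs in assoc.mapping.items()
    }
    fallback_pool = np.array(assoc.all_species, dtype=object)

    for i, stream in enumerate(rng_iter.spawn(n_iter)):
        species = base_species.copy()
        for v, pos in vern_groups.items():
            if v in resolve_alphas:
                names, alphas = resolve_alphas[v]
                species[pos] = names[stream.choice(len(names), size=len(pos), p=alphas)]
            else:
                species[pos] = fallback_pool[stream.integers(len(fallback_pool), size=len(pos))]

        if tm_sampled is not None:
            tm_full = assign_unsampled_species(all_species, tm_sampled, taxonomy, stream)
            _, dist_mat = standardize_and_distance(tm_full)
            sp_row = {s: j for j, s in enumerate(dist_mat.index)}
            dist_arr = dist_mat.to_numpy()
            trait_arr = tm_full.traits.loc[dist_mat.index, TRAITS].to_numpy()
            perm = stream.permutation(len(dist_arr))  # functional null relabelling
        else:
            sp_row, dist_arr, trait_arr, perm = {}, None, None, None

        recruited = set()
        for p in plots:
            pre_counts = _counts(species, pre_idx[(p,)])
            for j, t in enumerate(times):
                idx = cohort_idx.get((p, int(t)), np.empty(0, dtype=int))
                if len(idx) == 0:
                    for m in store:
                        store[m][p][i, j] = 0.0
                    for tr in TRAITS:
                        cwm_store[tr][p][i, j] = np.nan
                    diff_tax["richness"][p][i, j] = 0.0
                    diff_tax["evenness"][p][i, j] = 0.0
                    diff_fun[p][i, j] = 0.0
                    continue
                counts = _counts(species, idx)
                recruited.update(counts)
                store["richness"][p][i, j] = hill_diversity(counts, 0)
                store["evenness"][p][i, j] = hill_diversity(counts, 2)
                store["turnover"][p][i, j] = turnover(counts, pre_counts)
                rows = np.array([sp_row[s] for s in counts])
                pvec = np.array(list(counts.values()), dtype=float)
                pvec /= pvec.sum()
                sub = dist_arr[np.ix_(rows, rows)]
                rao_obs = float(pvec @ sub @ pvec)
                store["rao"][p][i, j] = rao_obs
                for k_t, tr in enumerate(TRAITS):
                    cwm_store[tr][p][i, j] = float(pvec @ trait_arr[rows, k_t])

                # taxonomic null: resample the standing community of (plot, year)
                comm = _counts(species, standing_idx[(p, int(t))])
                null_counts = taxonomic_null_draw(comm, int(len(idx)), stream)
                diff_tax["richness"][p][i, j] = store["richness"][p][i, j] - hill_diversity(
                    null_counts, 0
                )
                diff_tax["evenness"][p][i, j] = store["evenness"][p][i, j] - hill_diversity(
                    null_counts, 2
                )
                # functional null: permute trait rows (distance relabelling)
                rows_null = perm[rows]
                sub_null = dist_arr[np.ix_(rows_null, rows_null)]
                diff_fun[p][i, j] = rao_obs - float(pvec @ sub_null @ pvec)
        n_species_recruited[i] = len(recruited)

    # --- aggregation ---------------------------------------------------------
    def band(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return mat.mean(axis=0), np.percentile(mat, 2.5, axis=0), np.percentile(mat, 97.5, axis=0)

    div_rows, null_rows, turn_rows, cwm_rows = [], [], [], []
    for p in plots:
        for m in ("richness", "evenness", "rao"):
            mean, lo, hi = band(store[m][p])
            obs[m][p] = mean
            for j, t in enumerate(times):
                div_rows.append((p, int(t), m, mean[j], lo[j], hi[j]))
        mean, lo, hi = band(store["turnover"][p])
        obs["turnover"][p] = mean
        for j, t in enumerate(times):
            turn_rows.append((p, int(t), mean[j], lo[j], hi[j]))
        for m in ("richness", "evenness"):
            mean, lo, hi = band(diff_tax[m][p])
            for j, t in enumerate(times):
                null_rows.append(
                    (p, int(t), "taxonomic", m, mean[j], lo[j], hi[j], bool(lo[j] > 0 or hi[j] < 0))
                )
        mean, lo, hi = band(diff_fun[p])
        for j, t in enumerate(times):
            null_rows.append(
                (p, int(t), "functional", "rao", mean[j], lo[j], hi[j], bool(lo[j] > 0 or hi[j] < 0))
            )
        for tr in TRAITS:
            mean, lo, hi = band(cwm_store[tr][p])
            smooth = fit_smooth_trajectory(
                TrajectorySeries(p, times, mean, metric=f"cwm_{tr}")
            ).fitted
            for j, t in enumerate(times):
                cwm_rows.append((p, int(t), tr, mean[j], lo[j], hi[j], smooth[j]))

    diversity = pd.DataFrame(
        div_rows, columns=["plot_id", "time", "metric", "value", "ci_low", "ci_high"]
    )
    turn = pd.DataFrame(turn_rows, columns=["plot_id", "time", "value", "ci_low", "ci_high"])
    null_bands = pd.DataFrame(
        null_rows,
        columns=["plot_id", "time", "model", "metric", "diff_mean", "ci_low", "ci_high", "significant"],
    )
    cwm_df = pd.DataFrame(
        cwm_rows, columns=["plot_id", "time", "trait", "value", "ci_low", "ci_high", "smoothed"]
    )

    # --- breakpoints ---------------------------------------------------------
    bp_rows = []
    for p in plots:
        for m in ("richness", "evenness", "rao", "turnover"):
            model = detect_breakpoints(
                TrajectorySeries(p, times, obs[m][p], metric=m),
                max_breaks=cfg.max_breaks,
                min_seg=cfg.min_seg,
            )
            bp_rows.append(
                {
                    "plot_id": p,
                    "metric": m,
                    "n_breaks": model.n_breaks,
                    "break_times": ";".join(f"{b:g}" for b in model.break_times),
                    "slopes": ";".join(f"{s:.6g}" for _, s in model.segments),
                    "sse": model.sse,
                    "bic": model.bic,
                }
            )
    breakpoints = pd.DataFrame(bp_rows)

    # --- gradient correlations ----------------------------------------------
    agb_vec = np.array([agb[p] for p in plots])
    corr_rows = []

    def corr(name: str, summary: str, y: np.ndarray):
        rho, pval = spearman_test(agb_vec, y)
        corr_rows.append({"metric": name, "summary": summary, "rho": rho, "p_value": pval})

    corr("turnover", "max_value", np.array([obs["turnover"][p].max() for p in plots]))
    for m in ("richness", "evenness"):
        corr(
            m,
            "max_abs_null_diff",
            np.array(
                [abs(max_deviation(TrajectorySeries(p, times, diff_tax[m][p].mean(axis=0)), 0.0)[0]) for p in plots]
            ),
        )
    corr(
        "rao",
        "max_abs_null_diff",
        np.array(
            [abs(max_deviation(TrajectorySeries(p, times, diff_fun[p].mean(axis=0)), 0.0)[0]) for p in plots]
        ),
    )
    correlations = pd.DataFrame(corr_rows)

    cohort_sizes = (
        members.groupby(["plot_id", "time"], observed=True)
        .size()
        .rename("n_recruits")
        .reset_index()
    )
    manifest["stages"]["metrics"] = {
        "n_iter": n_iter,
        "n_species_recruited_mean": float(n_species_recruited.mean()),
    }
    manifest["runtime_s"] = round(time.time() - t_start, 2)
    manifest["config"] = {
        k: v
        for k, v in {
            **cfg.scenario.to_dict(),
            "interval": cfg.interval,
            "start_offset": cfg.start_offset,
            "horizon": cfg.horizon,
            "n_iter": cfg.n_iter,
        }.items()
    }

    result = PipelineResult(
        diversity=diversity,
        turnover=turn,
        cwm=cwm_df,
        null_bands=null_bands,
        breakpoints=breakpoints,
        correlations=correlations,
        cohort_sizes=cohort_sizes,
        association=assoc,
        disturbance=dist,
        manifest=manifest,
    )
    out = out_dir or cfg.out_dir
    if out:
        write_results(result, out)
    return result


def write_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.association.to_csv(out / "association.csv")
    result.cohort_sizes.to_csv(out / "cohorts.csv", index=False)
    result.diversity.to_csv(out / "diversity_trajectories.csv", index=False)
    result.turnover.to_csv(out / "turnover.csv", index=False)
    result.cwm.to_csv(out / "cwm_trajectories.csv", index=False)
    result.null_bands.to_csv(out / "null_bands.csv", index=False)
    result.breakpoints.to_csv(out / "breakpoints.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
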