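"""Taxonomic and functional null models for recruitment trajectories.

The taxonomic null asks: if recruits were a random sample of the
standing community of their plot and year, what diversity would we see?
It redraws, for each plot-time, as many stems as were actually recruited
from the whole community's relative abundances (a multinomial draw), so
sample size is conserved exactly and expected composition equals the
community's.

The functional null keeps the observed community but severs the link
between species and traits: whole trait rows (7-vectors) are permuted
uniformly across species labels, conserving the multiset of trait
syndromes while randomizing which abundance carries which syndrome.

For either null, 100 iterations of (null - observed) per time point give
a percentile 95% band; a time point is flagged significant when zero
falls outside the band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .trait_processing import TraitMatrix


@dataclass
class NullEnsemble:
    """iteration x time matrix of null metric values."""

    values: np.ndarray
    times: np.ndarray
    model: str  # "taxonomic" | "functional"

    @property
    def n_iter(self) -> int:
        return self.values.shape[0]


def taxonomic_null_draw(
    community: Mapping[str, int], n_recruits: int, rng: np.random.Generator
) -> dict[str, int]:
    """Multinomial draw of n_recruits stems from the community's frequencies."""
    if n_recruits <= 0:
        raise ValueError("n_recruits must be positive")
    species = [s for s, c in community.items() if c > 0]
    if not species:
        raise ValueError("empty community")
    counts = np.array([community[s] for s in species], dtype=float)
    draw = rng.multinomial(n_recruits, counts / counts.sum())
    return {s: int(k) for s, k in zip(species, draw) if k > 0}


def functional_null_draw(tm: TraitMatrix, rng: np.random.Generator) -> TraitMatrix:
    """Permute whole trait rows uniformly across species labels."""
    if not tm.complete:
        raise ValueError("functional null needs a complete trait matrix")
    perm = rng.permutation(len(tm.traits))
    shuffled = pd.DataFrame(
        tm.traits.to_numpy()[perm], index=tm.traits.index, columns=tm.traits.columns
    )
    return TraitMatrix(traits=shuffled, taxonomy=tm.taxonomy)


def null_band(
    observed: np.ndarray,
    times: np.ndarray,
    draw_metric_fn: Callable[[int, np.random.Generator], float],
    n_iter: int = 100,
    rng: np.random.Generator | None = None,
    model: str = "taxonomic",
    level: float = 0.95,
) -> tuple[NullEnsemble, pd.DataFrame]:
    """Null ensemble and percentile band of the observed-minus-null difference.

    ``draw_metric_fn(time_index, rng)`` must perform one null draw for
    that time point and return the metric value. The returned frame has
    per-time mean difference, the [2.5, 97.5] percentile interval (at the
    default level), and a significance flag set when 0 lies outside it.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2 to form a confidence interval")
    rng = np.random.default_rng() if rng is None else rng
    observed = np.asarray(observed, dtype=float)
    times = np.asarray(times)
    if observed.shape != times.shape:
        raise ValueError("observed and times must share their grid")
    values = np.empty((n_iter, len(times)))
    streams = rng.spawn(n_iter)
    for i, stream in enumerate(streams):
        for j in range(len(times)):
            values[i, j] = draw_metric_fn(j, stream)
    diff = observed[None, :] - values
    lo = (1.0 - level) / 2.0 * 100.0
    ci_low = np.percentile(diff, lo, axis=0)
    ci_high = np.percentile(diff, 100.0 - lo, axis=0)
    band = pd.DataFrame(
        {
            "time": times,
            "diff_mean": diff.mean(axis=0),
            "ci_low": ci_low,
            "ci_high": ci_high,
            "significant": (ci_low > 0.0) | (ci_high < 0.0),
        }
    )
    return NullEnsemble(values=values, times=times, model=model), band
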