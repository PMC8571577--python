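"""Community diversity and composition metrics.

All functions operate on abundance vectors: mappings ``species -> count``
(nonnegative integers, positive total). Relative frequencies
``p_s = count_s / total`` are derived internally.

Implemented metrics:

* Hill numbers of order 0 (species richness) and 2 (inverse Simpson
  concentration, the "effective number of dominant species", used as
  taxonomic evenness),
* Rao quadratic entropy ``H(P) = sum_{s'} sum_{s''} p_s' p_s'' d_{s's''}``
  over a functional dissimilarity matrix,
* community-weighted mean (CWM) trait values,
* relativized abundance replacement (Podani-style turnover):
  ``T_ab = (sum_i |x_ia - x_ib| - |sum_i x_ia - sum_i x_ib|)
  / sum_i max(x_ia, x_ib)``, the species-replacement component of
  abundance difference, scaled to [0, 1].
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["hill_diversity", "rao_entropy", "cwm", "turnover", "relative_frequencies"]


def _validate(a: Mapping[str, int]) -> dict[str, float]:
    if not a:
        raise ValueError("empty abundance vector")
    clean = {s: float(c) for s, c in a.items() if c > 0}
    if any(c < 0 for c in a.values()):
        raise ValueError("negative abundance")
    if not clean:
        raise ValueError("abundance vector with zero total")
    return clean


def relative_frequencies(a: Mapping[str, int]) -> dict[str, float]:
    """Relative frequencies p_s = count_s / total over species with count > 0."""
    clean = _validate(a)
    total = sum(clean.values())
    return {s: c / total for s, c in clean.items()}


def hill_diversity(a: Mapping[str, int], q: int) -> float:
    """Hill number of order q for an abundance vector.

    q = 0 is species richness; q = 2 is the inverse Simpson index
    1 / sum(p_s^2), the Hill transformation of Simpson concentration.
    Both are effective species numbers in [1, S].
    """
    clean = _validate(a)
    if q == 0:
        return float(len(clean))
    if q == 2:
        p = np.array(list(clean.values()))
        p = p / p.sum()
        return float(1.0 / np.sum(p * p))
    raise ValueError(f"unsupported diversity order q={q!r}; supported: 0, 2")


def rao_entropy(a: Mapping[str, int], d: pd.DataFrame) -> float:
    """Rao quadratic entropy: abundance-weighted mean pairwise dissimilarity.

    ``d`` is a symmetric species x species distance matrix (DataFrame with
    species on both axes) covering every species in ``a``. The full double
    sum includes the zero diagonal terms, so the value is 0 iff the
    community holds one species or all pairwise distances vanish.
    """
    freqs = relative_frequencies(a)
    species = sorted(freqs)
    missing = [s for s in species if s not in d.index]
    if missing:
        raise KeyError(f"species missing from distance matrix: {missing}")
    p = np.array([freqs[s] for s in species])
    sub = d.loc[species, species].to_numpy(dtype=float)
    return float(p @ sub @ p)


def cwm(a: Mapping[str, int], tm: pd.DataFrame) -> pd.Series:
    """Community-weighted mean traits: per trait, sum_s p_s * trait_t(s).

    ``tm`` is a complete species x trait DataFrame in raw (native) units;
    the result is a Series over its trait columns.
    """
    freqs = relative_frequencies(a)
    species = sorted(freqs)
    missing = [s for s in species if s not in tm.index]
    if missing:
        raise KeyError(f"species missing from trait matrix: {missing}")
    if tm.loc[species].isna().any().any():
        raise ValueError("trait matrix has missing values for community species")
    p = np.array([freqs[s] for s in species])
    return pd.Series(p @ tm.loc[species].to_numpy(dtype=float), index=tm.columns)


def turnover(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    """Relativized abundance replacement between two communities, in [0, 1].

    Absent species count as zero; the index set is the species union.
    Symmetric in its arguments; 0 for identical or purely nested
    communities, 1 for disjoint communities of equal total size.
    """
    ca, cb = _validate(a), _validate(b)
    union = set(ca) | set(cb)
    xa = np.array([ca.get(s, 0.0) for s in union])
    xb = np.array([cb.get(s, 0.0) for s in union])
    denom = np.maximum(xa, xb).sum()
    value = (np.abs(xa - xb).sum() - abs(xa.sum() - xb.sum())) / denom
    # clip floating noise at the boundaries
    return float(min(max(value, 0.0), 1.0))
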