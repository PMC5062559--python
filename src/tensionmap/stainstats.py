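"""Antibody-stain pixel correlations and nonparametric group comparisons.

Stain analysis correlates the antibody channel of a fixed, stained cell
with the inverted FRET ratio over stringently selected pixels (in the cell
mask and more than 4 background s.d. above background in both donor and
FRET channels). Because Pearson correlation is invariant to affine maps,
inversion is implemented as negation; only the sign convention matters
(tension lowers the ratio, so a stain that marks tension-bearing receptors
correlates positively with the inverted ratio).

Group comparisons are nonparametric throughout: Mann-Whitney U for
pairwise designs, Kruskal-Wallis followed by Dunn's multiple-comparison
test (rank-based z statistics with tie correction and Bonferroni
family-wise adjustment) for multi-group designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .maps import RatioMap
from .prep import BackgroundStats

__all__ = [
    "StainCorrelation",
    "stain_pixel_correlation",
    "group_compare",
    "dunn_posthoc",
]


@dataclass
class StainCorrelation:
    """Pixel-wise Pearson correlation of antibody vs inverted FRET ratio."""

    cell_id: str
    r: float
    n_pixels: int
    k_sigma: float
    channel_pair: str = "antibody-vs-inverted-ratio"


def stain_pixel_correlation(
    antibody: np.ndarray,
    ratio_map: RatioMap,
    cell_mask: np.ndarray,
    donor: np.ndarray,
    fret: np.ndarray,
    bg_donor: BackgroundStats,
    bg_fret: BackgroundStats,
    k: float = 4.0,
    min_pixels: int = 100,
    cell_id: str = "cell",
) -> StainCorrelation:
    """Pearson r between antibody intensity and the inverted FRET ratio.

    Eligible pixels lie in the cell mask, are valid in the ratio map, and
    exceed ``mu + k*sigma`` of the background in both the donor and FRET
    channels (``k`` = 4 by default; raising k never adds pixels).
    """
    mask = np.asarray(cell_mask, dtype=bool)
    elig = (
        mask
        & ratio_map.valid
        & (np.asarray(donor, float) > bg_donor.mu + k * bg_donor.sigma)
        & (np.asarray(fret, float) > bg_fret.mu + k * bg_fret.sigma)
    )
    n = int(elig.sum())
    if n < min_pixels:
        raise ValueError(f"only {n} eligible pixels (need >= {min_pixels})")
    inv = -ratio_map.ratio[elig]
    ab = np.asarray(antibody, dtype=float)[elig]
    r = float(np.corrcoef(ab, inv)[0, 1])
    return StainCorrelation(cell_id, r, n, k)


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return ranks, tie_term


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test after Kruskal-Wallis.

    For each pair (i, j): z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 -
    T/(12(N-1))) * (1/n_i + 1/n_j)) with tie term T = sum(t^3 - t); p
    values are two-sided normal tails, family-wise adjusted (Bonferroni).
    """
    names = list(groups)
    sizes = {k: len(groups[k]) for k in names}
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    N = pooled.size
    ranks, tie_term = _rank_with_ties(pooled)
    mean_ranks = {}
    i0 = 0
    for k in names:
        mean_ranks[k] = ranks[i0 : i0 + sizes[k]].mean()
        i0 += sizes[k]
    tie_corr = tie_term / (12.0 * (N - 1))
    rows = []
    pairs = list(combinations(names, 2))
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt((N * (N + 1) / 12.0 - tie_corr) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p, "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def group_compare(samples: dict[str, np.ndarray], design: str = "auto") -> dict:
    """Nonparametric comparison of condition groups.

    ``design`` "pairwise" runs a two-sided Mann-Whitney U (requires exactly
    two groups); "multi" runs Kruskal-Wallis plus Dunn's corrected pairwise
    tests; "auto" picks by group count. Every group needs >= 3 values.

    Returns a dict report: for pairwise {test, U, p, n}; for multi
    {test, H, p, pairwise: DataFrame}.
    """
    if not samples or any(len(v) == 0 for v in samples.values()):
        raise ValueError("empty group")
    if any(len(v) < 3 for v in samples.values()):
        raise ValueError("each group needs >= 3 values")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if design == "auto":
        design = "pairwise" if len(groups) == 2 else "multi"
    if design == "pairwise":
        if len(groups) != 2:
            raise ValueError("pairwise design requires exactly 2 groups")
        (ka, va), (kb, vb) = groups.items()
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        return {
            "test": "mann-whitney", "groups": (ka, kb),
            "U": float(res.statistic), "p": float(res.pvalue),
            "n": (len(va), len(vb)),
        }
    if design == "multi":
        H, p = stats.kruskal(*groups.values())
        return {
            "test": "kruskal-wallis", "H": float(H), "p": float(p),
            "pairwise": dunn_posthoc(groups),
        }
    raise ValueError(f"unknown design {design!r}")
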