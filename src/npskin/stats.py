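"""Rank-based group comparison: Kruskal-Wallis wrapper and Dunn post hoc.

The Dunn test compares mean ranks of group pairs after a significant
Kruskal-Wallis H, with the tie-corrected large-sample z statistic

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )

where ``T = sum(t^3 - t)`` over tie groups.  P-values are two-sided
normal and adjusted for multiple comparisons (Holm by default).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p across the given groups."""
    groups = [np.asarray(g, float) for g in groups]
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0  # no rank variation
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_test(groups, labels=None, p_adjust: str = "holm") -> pd.DataFrame:
    """Pairwise Dunn z tests over the groups.

    Returns a frame with one row per unordered pair: mean-rank
    difference, z, raw and adjusted two-sided p.
    """
    groups = [np.asarray(g, float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({
            "group_a": labels[i], "group_b": labels[j],
            "mean_rank_diff": mean_ranks[i] - mean_ranks[j],
            "z": z, "p_raw": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = np.maximum(
            multipletests(out["p_raw"].to_numpy(), method=p_adjust)[1],
            out["p_raw"].to_numpy(),
        )
    return out
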