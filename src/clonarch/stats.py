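"""Shared statistical helpers: BH adjustment and Wilcoxon rank-sum P values.

The rank-sum helper exists because the permutation machinery needs the same
discrepancy measure evaluated identically for the observed data and for
thousands of permuted carrier sets; a vectorised midrank/normal-approximation
path keeps that affordable, while tiny groups fall back to SciPy's exact
test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (monotone step-up), NaN-safe."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    n = pm.size
    if n == 0:
        return q
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qm = np.empty(n)
    qm[order] = np.minimum(ranked, 1.0)
    q[mask] = qm
    return q


def midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    return sps.rankdata(x, method="average")


def rank_sum_p_greater(
    values: np.ndarray, carrier_mask: np.ndarray, exact_max_n: int = 20
) -> float:
    """One-tailed Wilcoxon rank-sum P for carriers having HIGHER values.

    Exact null enumeration (SciPy) when both groups have <= ``exact_max_n``
    observations and there are no ties; midrank normal approximation with
    continuity correction otherwise.
    """
    values = np.asarray(values, dtype=float)
    carrier_mask = np.asarray(carrier_mask, dtype=bool)
    x = values[carrier_mask]
    y = values[~carrier_mask]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if (
        x.size <= exact_max_n
        and y.size <= exact_max_n
        and np.unique(values).size == values.size
    ):
        return float(
            sps.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
        )
    ranks = midranks(values)
    return float(
        _normal_p_greater(
            np.array([ranks[carrier_mask].sum()]), ranks, int(x.size)
        )[0]
    )


def _normal_p_greater(
    carrier_rank_sums: np.ndarray, ranks: np.ndarray, n1: int
) -> np.ndarray:
    """Normal-approximation one-tailed P from carrier rank sums.

    ``ranks`` are the midranks of the pooled values (length N); ``n1`` is the
    carrier group size. Tie correction uses the pooled tie structure.
    """
    n = ranks.size
    n2 = n - n1
    u = carrier_rank_sums - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return np.ones_like(u, dtype=float)
    z = (u - mu - 0.5) / np.sqrt(var)
    return sps.norm.sf(z)


def rank_sum_p_greater_many(
    values: np.ndarray, carrier_masks: np.ndarray
) -> np.ndarray:
    """Vectorised one-tailed rank-sum P (carriers higher) over many carrier
    sets of a fixed size against one pooled value vector.

    ``carrier_masks`` is a boolean matrix (n_sets x N); every row must have
    the same number of carriers.
    """
    values = np.asarray(values, dtype=float)
    masks = np.asarray(carrier_masks, dtype=bool)
    n1 = int(masks[0].sum())
    if not np.all(masks.sum(axis=1) == n1):
        raise ValueError("all carrier sets must have equal size")
    ranks = midranks(values)
    rank_sums = masks @ ranks
    return _normal_p_greater(rank_sums, ranks, n1)
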