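"""Single-sample gene-set enrichment (ssGSEA) scoring of immune cell-type
gene sets.

For one sample, genes are ranked by expression (descending; ties broken by
gene name for determinism). Walking down the ranking, the in-set empirical
CDF accumulates weight |rank value|^w for set members (rank value = N for
the top gene down to 1) and the out-of-set ECDF accumulates uniformly; the
enrichment score is the sum over all positions of (ECDF_in - ECDF_out).
With w = 0 this reduces to a pure rank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust


@dataclass(frozen=True)
class SsgseaScore:
    sample_id: str
    cell_type: str
    score: float
    n_set_genes_used: int


def ssgsea_score(
    expression: pd.Series,
    gene_set: Iterable[str],
    weight: float = 0.25,
    sample_id: str = "",
    cell_type: str = "",
) -> SsgseaScore:
    """Running-sum enrichment score of ``gene_set`` in one sample's
    expression profile."""
    if expression.size < 2:
        raise ValueError("need at least two genes")
    genes_in_set = set(gene_set) & set(expression.index)
    if not genes_in_set:
        raise ValueError("gene set does not intersect the expression profile")
    if len(genes_in_set) == expression.size:
        raise ValueError("gene set covers all genes; out-of-set ECDF undefined")
    # descending expression, gene-name ascending on ties
    order = sorted(expression.index, key=lambda g: (-expression[g], g))
    n = len(order)
    in_set = np.array([g in genes_in_set for g in order])
    rank_values = np.arange(n, 0, -1, dtype=float)  # N .. 1
    w_in = np.where(in_set, np.abs(rank_values) ** weight, 0.0)
    ecdf_in = np.cumsum(w_in) / w_in.sum()
    out = (~in_set).astype(float)
    ecdf_out = np.cumsum(out) / out.sum()
    score = float((ecdf_in - ecdf_out).sum())
    return SsgseaScore(sample_id, cell_type, score, len(genes_in_set))


def ssgsea_matrix(
    expression: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    weight: float = 0.25,
) -> pd.DataFrame:
    """Scores for every (cell type, sample): cell types x samples."""
    rows = {}
    for cell_type, genes in gene_sets.items():
        rows[cell_type] = [
            ssgsea_score(
                expression[s], genes, weight, sample_id=s, cell_type=cell_type
            ).score
            for s in expression.columns
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(expression.columns)
    )


def compare_immune(scores: pd.DataFrame, group_labels: pd.Series) -> pd.DataFrame:
    """Two-sided rank-sum comparison of each cell type's scores between two
    groups, BH-adjusted across cell types.

    ``scores`` is cell types x samples; ``group_labels`` maps samples to two
    group values.
    """
    groups = sorted(group_labels.unique())
    if len(groups) != 2:
        raise ValueError("compare_immune requires exactly two groups")
    g1, g2 = groups
    a_samples = group_labels.index[group_labels == g1]
    b_samples = group_labels.index[group_labels == g2]
    if len(a_samples) == 0 or len(b_samples) == 0:
        raise ValueError("one group is empty")
    rows = []
    for cell_type in scores.index:
        x = scores.loc[cell_type, a_samples].to_numpy(dtype=float)
        y = scores.loc[cell_type, b_samples].to_numpy(dtype=float)
        method = "exact" if max(len(x), len(y)) <= 20 else "auto"
        p = float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        )
        rows.append(
            (cell_type, float(np.median(x)), float(np.median(y)), p)
        )
    df = pd.DataFrame(rows, columns=["cell_type", f"median_{g1}", f"median_{g2}", "p"])
    df["q"] = bh_adjust(df["p"])
    return df
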