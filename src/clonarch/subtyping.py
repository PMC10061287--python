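"""Molecular subtyping from the clonal-architecture feature matrix.

The feature matrix holds, per sample, the CCF of each driver gene (maximum
CCF over its non-silent mutations) and of each frequent arm-level SCNA
(length-weighted mean segment CCF); absent events are 0. Rank-2 NMF with
Lee-Seung multiplicative updates (squared Euclidean loss) factorises this
matrix; each sample's cluster is the argmax of its coefficient column.
Clusters are contrasted with Fisher's exact test (binary features) and the
two-sided Wilcoxon rank-sum test (continuous metrics), BH-adjusted within
each family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust


def build_ccf_matrix(
    gene_calls: pd.DataFrame,
    arm_events: pd.DataFrame,
    samples: Sequence[str],
) -> pd.DataFrame:
    """Assemble the features x samples CCF matrix.

    ``gene_calls`` needs columns (sample_id, gene, ccf) for non-silent
    mutations; ``arm_events`` needs (sample_id, feature, ccf). The gene entry
    is the maximum CCF among the gene's mutations in that sample; arm entries
    are taken as given. Samples without events keep all-zero columns.
    """
    gene_part = (
        gene_calls.groupby(["gene", "sample_id"])["ccf"].max().unstack(fill_value=0.0)
        if len(gene_calls)
        else pd.DataFrame()
    )
    arm_part = (
        arm_events.set_index(["feature", "sample_id"])["ccf"].unstack(fill_value=0.0)
        if len(arm_events)
        else pd.DataFrame()
    )
    X = pd.concat([gene_part, arm_part]).reindex(columns=list(samples), fill_value=0.0)
    X = X.fillna(0.0)
    if X.index.duplicated().any():
        dupes = sorted(X.index[X.index.duplicated()])
        raise ValueError(f"duplicate feature names: {dupes[:5]}")
    if ((X.to_numpy() < 0) | (X.to_numpy() > 1)).any():
        raise ValueError("CCF entries must lie in [0, 1]")
    return X


@dataclass
class SubtypeSolution:
    basis: pd.DataFrame  # features x K
    coefficients: pd.DataFrame  # K x samples
    labels: pd.Series  # per sample, cluster index 1..K
    K: int
    objective: List[float] = field(default_factory=list)


def nmf_lee(
    X: pd.DataFrame,
    K: int = 2,
    n_restarts: int = 10,
    tol: float = 1e-9,
    rng_seed: int = 0,
    max_iter: int = 2000,
) -> SubtypeSolution:
    """Lee-Seung multiplicative-update NMF minimising ||X - WH||_F^2.

    The best of ``n_restarts`` random initialisations (by final objective) is
    kept; sample labels are the argmax coefficient row. Deterministic given
    ``rng_seed``.
    """
    V = X.to_numpy(dtype=float)
    if np.any(V < 0):
        raise ValueError("NMF input must be non-negative")
    F, N = V.shape
    if K > min(F, N):
        raise ValueError(f"K={K} exceeds min(matrix dimensions)={min(F, N)}")
    eps = np.finfo(float).tiny
    root = np.random.default_rng(rng_seed)
    best = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        scale = np.sqrt(max(V.mean(), eps) / K)
        W = scale * (0.5 + rng.random((F, K)))
        H = scale * (0.5 + rng.random((K, N)))
        trace = [float(((V - W @ H) ** 2).sum())]
        for _ in range(max_iter):
            H *= (W.T @ V) / (W.T @ W @ H + eps)
            W *= (V @ H.T) / (W @ H @ H.T + eps)
            obj = float(((V - W @ H) ** 2).sum())
            if obj > trace[-1] + 1e-9 * (abs(trace[-1]) + 1):
                raise RuntimeError("NMF objective increased")
            done = abs(trace[-1] - obj) <= tol * (abs(trace[-1]) + eps)
            trace.append(obj)
            if done:
                break
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best
    labels = pd.Series(np.argmax(H, axis=0) + 1, index=X.columns, name="cluster")
    names = [f"F{k + 1}" for k in range(K)]
    return SubtypeSolution(
        basis=pd.DataFrame(W, index=X.index, columns=names),
        coefficients=pd.DataFrame(H, index=names, columns=X.columns),
        labels=labels,
        K=K,
        objective=trace,
    )


def name_clusters(labels: pd.Series, severity_metric: pd.Series) -> pd.Series:
    """Canonical two-cluster naming: the cluster with the higher mean of
    ``severity_metric`` (e.g. arm-level SCNA burden) is named "A", the other
    "B". Removes the NMF label-swap ambiguity."""
    values = sorted(labels.unique())
    if len(values) != 2:
        raise ValueError("canonical naming is defined for exactly two clusters")
    means = {v: severity_metric.reindex(labels.index[labels == v]).mean() for v in values}
    a = max(values, key=lambda v: (means[v], -v))
    return labels.map(lambda v: "A" if v == a else "B").rename("subtype")


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, bool]:
    """Sample odds ratio of [[a,b],[c,d]]; Haldane +0.5 correction when any
    cell is 0, flagged in the second return value."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def contrast_clusters(
    labels: pd.Series,
    feature_carriers: Optional[pd.DataFrame] = None,
    continuous_metrics: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Compare two clusters on binary features and continuous metrics.

    ``labels`` maps samples to "A"/"B" (or two arbitrary values);
    ``feature_carriers`` is features x samples binary; ``continuous_metrics``
    is samples x metrics. Returns (binary_contrasts, metric_contrasts), each
    BH-adjusted within its family.
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("contrast requires exactly two clusters")
    g1, g2 = groups
    in_a = labels == g1
    samples_a = labels.index[in_a]
    samples_b = labels.index[~in_a]
    binary_rows = []
    if feature_carriers is not None:
        for feature in feature_carriers.index:
            row = feature_carriers.loc[feature]
            a = int(row[samples_a].sum())
            b = int(len(samples_a) - a)
            c = int(row[samples_b].sum())
            d = int(len(samples_b) - c)
            orr, corrected = odds_ratio_2x2(a, b, c, d)
            p = sps.fisher_exact([[a, b], [c, d]])[1]
            binary_rows.append(
                (feature, a / len(samples_a), c / len(samples_b), orr, corrected, p)
            )
    binary = pd.DataFrame(
        binary_rows,
        columns=[
            "feature",
            f"prevalence_{g1}",
            f"prevalence_{g2}",
            "odds_ratio",
            "haldane_corrected",
            "fisher_p",
        ],
    )
    if len(binary):
        binary["q"] = bh_adjust(binary["fisher_p"])
    cont_rows = []
    if continuous_metrics is not None:
        for metric in continuous_metrics.columns:
            x = continuous_metrics.loc[samples_a, metric].dropna()
            y = continuous_metrics.loc[samples_b, metric].dropna()
            if len(x) == 0 or len(y) == 0:
                raise ValueError(f"metric {metric} empty in one cluster")
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            cont_rows.append((metric, float(x.median()), float(y.median()), p))
    cont = pd.DataFrame(
        cont_rows, columns=["metric", f"median_{g1}", f"median_{g2}", "p"]
    )
    if len(cont):
        cont["q"] = bh_adjust(cont["p"])
    return binary, cont
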