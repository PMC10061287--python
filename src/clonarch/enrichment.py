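"""Gene-signature association testing with margins-preserving matrix
randomization.

The null model is the fixed-margins ensemble of the binary gene x sample
mutation matrix: permuted matrices keep every gene's carrier count and every
sample's mutation count exactly as observed, removing the confounding between
per-sample mutation burden and signature activity. Randomization uses the
curveball algorithm (repeated "trades" of unique carriers between random
gene pairs), which converges to the uniform distribution over the ensemble.

The discrepancy measure per (gene, signature) pair is the one-tailed
Wilcoxon rank-sum P comparing signature activity in carriers vs
non-carriers (carriers higher); the permutation P is the fraction of
permuted matrices whose rank-sum P is at least as extreme (<=) as the
observed one, with a +1 correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import MutationRecord
from .stats import bh_adjust, midranks, rank_sum_p_greater, rank_sum_p_greater_many

logger = logging.getLogger(__name__)


@dataclass
class SigEnrichResult:
    gene: str
    signature: str
    n_carriers: int
    delta_median: float
    p_perm: float
    q: float = float("nan")
    untestable: bool = False


def mutation_matrix(
    mutations: Iterable[MutationRecord],
    samples: Sequence[str],
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Binary genes x samples matrix of non-silent mutation carriage."""
    carriers: Dict[str, Set[str]] = {}
    for m in mutations:
        if m.variant_class == "silent":
            continue
        carriers.setdefault(m.gene, set()).add(m.sample_id)
    if genes is None:
        genes = sorted(carriers)
    data = np.zeros((len(genes), len(samples)), dtype=int)
    sample_idx = {s: j for j, s in enumerate(samples)}
    for i, g in enumerate(genes):
        for s in carriers.get(g, ()):
            if s in sample_idx:
                data[i, sample_idx[s]] = 1
    return pd.DataFrame(data, index=list(genes), columns=list(samples))


def select_test_genes(
    mutation_matrix_df: pd.DataFrame,
    panel_lists: Sequence[Iterable[str]] = (),
    min_freq: float = 0.05,
) -> List[str]:
    """Genes to test: union of genes at >= ``min_freq`` non-silent carrier
    frequency and the supplied panels (e.g. SMGs, APOBEC family, DNA-repair
    genes). Panel genes absent from the matrix are dropped with a log note."""
    freq = mutation_matrix_df.mean(axis=1)
    selected = set(freq.index[freq >= min_freq])
    for panel in panel_lists:
        for gene in panel:
            if gene in mutation_matrix_df.index:
                selected.add(gene)
            else:
                logger.warning("panel gene %s absent from mutation matrix", gene)
    if not selected:
        raise ValueError("no gene passes the selection filter")
    return sorted(selected)


def _validate_binary(M: np.ndarray) -> None:
    if not np.isin(M, (0, 1)).all():
        raise ValueError("mutation matrix must be binary")


def _curveball_rows(rows: List[Set[int]], n_trades: int, rng) -> None:
    """In-place curveball trades on a list of row-sets of column indices."""
    n_rows = len(rows)
    pairs = rng.integers(0, n_rows, size=(n_trades, 2))
    for i, j in pairs:
        if i == j:
            continue
        ri, rj = rows[i], rows[j]
        only_i = list(ri - rj)
        only_j = list(rj - ri)
        n_i = len(only_i)
        if n_i == 0 or len(only_j) == 0:
            continue
        pool = only_i + only_j
        perm = rng.permutation(len(pool))
        new_i = {pool[k] for k in perm[:n_i]}
        new_j = {pool[k] for k in perm[n_i:]}
        shared = ri & rj
        rows[i] = shared | new_i
        rows[j] = shared | new_j


def curveball_randomize(
    M: pd.DataFrame,
    n_trades: Optional[int] = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """One margins-preserving randomization of a binary matrix.

    Row and column sums are preserved exactly on every draw; with enough
    trades (default 5x the number of rows) the result approaches a uniform
    draw from the fixed-margins ensemble.
    """
    arr = M.to_numpy()
    _validate_binary(arr)
    rng = np.random.default_rng(rng_seed)
    rows = [set(np.flatnonzero(arr[i])) for i in range(arr.shape[0])]
    if n_trades is None:
        n_trades = 5 * arr.shape[0]
    _curveball_rows(rows, n_trades, rng)
    out = np.zeros_like(arr)
    for i, cols in enumerate(rows):
        out[i, list(cols)] = 1
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def curveball_ensemble(
    M: pd.DataFrame,
    n_draws: int,
    n_trades: Optional[int] = None,
    rng_seed: int = 0,
    burn_in_factor: int = 5,
) -> np.ndarray:
    """Stack of ``n_draws`` randomized matrices (n_draws x genes x samples).

    A single chain is used: an initial burn-in of ``burn_in_factor`` x
    ``n_trades`` trades, then ``n_trades`` trades between consecutive draws.
    """
    arr = M.to_numpy()
    _validate_binary(arr)
    rng = np.random.default_rng(rng_seed)
    if n_trades is None:
        n_trades = 5 * arr.shape[0]
    rows = [set(np.flatnonzero(arr[i])) for i in range(arr.shape[0])]
    _curveball_rows(rows, burn_in_factor * n_trades, rng)
    out = np.zeros((n_draws, *arr.shape), dtype=bool)
    for d in range(n_draws):
        _curveball_rows(rows, n_trades, rng)
        for i, cols in enumerate(rows):
            out[d, i, list(cols)] = True
    return out


def _null_ranksum_ps(
    activity: np.ndarray, masks: np.ndarray, exact_max_n: int = 20
) -> np.ndarray:
    """One-tailed rank-sum P for each permuted carrier mask, using the same
    method (exact for tiny groups, midrank normal approximation otherwise)
    as the observed statistic."""
    n = activity.size
    n1 = int(masks[0].sum())
    if max(n1, n - n1) <= exact_max_n and np.unique(activity).size == n:
        return np.array(
            [
                sps.mannwhitneyu(
                    activity[m], activity[~m], alternative="greater", method="exact"
                ).pvalue
                for m in masks
            ]
        )
    return rank_sum_p_greater_many(activity, masks)


def signature_enrichment_test(
    M: pd.DataFrame,
    activities: pd.Series,
    gene: str,
    signature: str = "",
    n_perm: int = 10000,
    rng_seed: int = 0,
    ensemble: Optional[np.ndarray] = None,
) -> SigEnrichResult:
    """Permutation test of association between one gene's mutation status and
    one signature's activity.

    ``activities`` is the per-sample mutation burden attributed to the
    signature (indexed like the columns of ``M``). A precomputed curveball
    ``ensemble`` can be shared across genes and signatures.
    """
    if gene not in M.index:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    act = activities.reindex(M.columns).to_numpy(dtype=float)
    if np.isnan(act).any():
        raise ValueError("activities missing for some samples")
    obs_mask = M.loc[gene].to_numpy(dtype=bool)
    n_car = int(obs_mask.sum())
    if n_car == 0 or n_car == M.shape[1]:
        return SigEnrichResult(
            gene, signature, n_car, float("nan"), float("nan"), untestable=True
        )
    delta = float(np.median(act[obs_mask]) - np.median(act[~obs_mask]))
    if ensemble is None:
        ensemble = curveball_ensemble(M, n_perm, rng_seed=rng_seed)
    gene_row = int(np.flatnonzero(M.index == gene)[0])
    masks = ensemble[:, gene_row, :]
    p_obs = rank_sum_p_greater(act, obs_mask)
    p_null = _null_ranksum_ps(act, masks)
    p_perm = (1 + int((p_null <= p_obs).sum())) / (len(p_null) + 1)
    return SigEnrichResult(gene, signature, n_car, delta, p_perm)


def signature_enrichment_table(
    M: pd.DataFrame,
    activity_df: pd.DataFrame,
    genes: Optional[Sequence[str]] = None,
    n_perm: int = 10000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Run the enrichment test for every (gene, signature) pair, sharing one
    curveball ensemble, and BH-adjust across all testable pairs.

    ``activity_df`` is samples x signatures (attributed mutation counts).
    """
    if genes is None:
        genes = list(M.index)
    ensemble = curveball_ensemble(M, n_perm, rng_seed=rng_seed)
    results: List[SigEnrichResult] = []
    for gene in genes:
        for signature in activity_df.columns:
            results.append(
                signature_enrichment_test(
                    M,
                    activity_df[signature],
                    gene,
                    signature=signature,
                    n_perm=n_perm,
                    rng_seed=rng_seed,
                    ensemble=ensemble,
                )
            )
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "signature": [r.signature for r in results],
            "n_carriers": [r.n_carriers for r in results],
            "delta_median": [r.delta_median for r in results],
            "p_perm": [r.p_perm for r in results],
            "untestable": [r.untestable for r in results],
        }
    )
    df["q"] = bh_adjust(df["p_perm"])
    return df
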