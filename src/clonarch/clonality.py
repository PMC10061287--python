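"""Cancer cell fraction (CCF) posteriors, clonality calls, and
clonal/subclonal enrichment statistics.

The CCF model: for an event observed with ``alt`` of ``depth`` reads in a
tumor of purity ``rho`` on a segment with integer allelic copies
``(major, minor)``, the expected variant allele fraction at cancer cell
fraction ``c`` is

    f(c) = rho * m * c / (rho * (major + minor) + (1 - rho) * 2)

with mutation multiplicity ``m`` estimated from the observed VAF and clamped
to [1, major]. The posterior is the binomial likelihood of ``alt`` given
``f(c)`` on a uniform 100-point grid c = 0.01 ... 1.00, normalised under a
flat prior. An event is *clonal* when the posterior mass at c >= 0.95
exceeds 0.5, *subclonal* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .stats import bh_adjust

CCF_GRID = np.round(np.arange(1, 101) / 100.0, 2)
# Extended grid used internally: likelihood mass from "super-clonal" fits
# (observed VAF above the clonal expectation, from sampling noise or a
# mis-specified multiplicity) is folded into the CCF = 1 bin, mirroring the
# clonal-peak handling of purity/ploidy callers.
_EXT_GRID = np.arange(1, 201) / 100.0
_CLONAL_CCF = 0.95
_CLONAL_PROB = 0.5


@dataclass
class CcfPosterior:
    event_id: str
    grid: np.ndarray
    posterior: np.ndarray
    ccf_map: float
    p_ge_095: float
    clonality: str

    def __post_init__(self) -> None:
        total = float(self.posterior.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior sums to {total}, not 1")


@dataclass
class EnrichmentPermResult:
    feature: str
    n_clonal: int
    n_subclonal: int
    observed_ratio: float
    p_clonal: float
    p_subclonal: float
    q: float = float("nan")


def estimate_multiplicity(
    alt_count: int, depth: int, purity: float, major: int, minor: int
) -> int:
    """Multiplicity m = clamp(round(vaf * D / purity), 1, major) where D is
    the purity-weighted total local copy number."""
    vaf = alt_count / depth
    denom = purity * (major + minor) + (1.0 - purity) * 2.0
    return int(np.clip(round(vaf * denom / purity), 1, major))


def ccf_posterior(
    alt_count: int,
    depth: int,
    purity: float,
    major: int,
    minor: int,
    event_id: str = "",
) -> CcfPosterior:
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0,1]")
    if major < 1 or minor < 0 or major < minor:
        raise ValueError("require major >= max(minor, 1) and minor >= 0")
    if not (0 <= alt_count <= depth):
        raise ValueError("require 0 <= alt_count <= depth")
    m = estimate_multiplicity(alt_count, depth, purity, major, minor)
    denom = purity * (major + minor) + (1.0 - purity) * 2.0
    f = purity * m * _EXT_GRID / denom
    f = np.clip(f, 1e-12, 1.0 - 1e-12)
    loglik = alt_count * np.log(f) + (depth - alt_count) * np.log1p(-f)
    ext = np.exp(loglik - logsumexp(loglik))
    post = ext[:100].copy()
    post[-1] += ext[100:].sum()  # fold super-clonal mass into CCF = 1
    post /= post.sum()
    p95 = float(post[CCF_GRID >= _CLONAL_CCF - 1e-12].sum())
    idx = int(np.argmax(post))
    return CcfPosterior(
        event_id=event_id,
        grid=CCF_GRID,
        posterior=post,
        ccf_map=float(CCF_GRID[idx]),
        p_ge_095=p95,
        clonality="clonal" if p95 > _CLONAL_PROB else "subclonal",
    )


def classify_clonality(post: CcfPosterior) -> str:
    """Clonal iff Pr(CCF >= 0.95) strictly exceeds 0.5."""
    return "clonal" if post.p_ge_095 > _CLONAL_PROB else "subclonal"


def ccf_posteriors_batch(
    alt: np.ndarray,
    depth: np.ndarray,
    purity: np.ndarray,
    major: np.ndarray,
    minor: np.ndarray,
) -> pd.DataFrame:
    """Vectorised MAP CCF / Pr(CCF>=0.95) / clonality for many events.

    Returns a DataFrame with columns ccf_map, p_ge_095, clonality.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    purity = np.asarray(purity, dtype=float)
    major = np.asarray(major, dtype=float)
    minor = np.asarray(minor, dtype=float)
    if np.any(depth < 1):
        raise ValueError("depth must be >= 1")
    if np.any((purity <= 0) | (purity > 1)):
        raise ValueError("purity must be in (0,1]")
    denom = purity * (major + minor) + (1.0 - purity) * 2.0
    vaf = alt / depth
    mult = np.clip(np.round(vaf * denom / purity), 1, major)
    f = (purity * mult)[:, None] * _EXT_GRID[None, :] / denom[:, None]
    f = np.clip(f, 1e-12, 1.0 - 1e-12)
    loglik = alt[:, None] * np.log(f) + (depth - alt)[:, None] * np.log1p(-f)
    loglik -= loglik.max(axis=1, keepdims=True)
    ext = np.exp(loglik)
    ext /= ext.sum(axis=1, keepdims=True)
    post = ext[:, :100].copy()
    post[:, -1] += ext[:, 100:].sum(axis=1)  # fold super-clonal mass
    post /= post.sum(axis=1, keepdims=True)
    p95 = post[:, CCF_GRID >= _CLONAL_CCF - 1e-12].sum(axis=1)
    ccf_map = CCF_GRID[np.argmax(post, axis=1)]
    return pd.DataFrame(
        {
            "ccf_map": ccf_map,
            "p_ge_095": p95,
            "clonality": np.where(p95 > _CLONAL_PROB, "clonal", "subclonal"),
        }
    )


def cohort_clonality_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Subclonal fraction per event class.

    ``calls`` needs columns ``event_class`` (e.g. snv / indel / scna) and
    ``clonality`` ("clonal"/"subclonal").
    """
    if calls.empty:
        raise ValueError("no clonality calls supplied")
    rows = []
    for cls, grp in calls.groupby("event_class", sort=True):
        n_sub = int((grp["clonality"] == "subclonal").sum())
        n_tot = len(grp)
        rows.append((cls, n_tot - n_sub, n_sub, n_sub / n_tot))
    return pd.DataFrame(
        rows, columns=["event_class", "n_clonal", "n_subclonal", "subclonal_fraction"]
    )


def clonal_enrichment_test(
    feature_calls: Sequence[str],
    all_calls: Sequence[str],
    n_perm: int = 10000,
    rng_seed: int = 0,
    feature: str = "",
) -> EnrichmentPermResult:
    """Permutation test for clonal (and, symmetrically, subclonal) enrichment
    of one feature's events against the cohort-wide clonality pool.

    Each permutation redraws the feature's labels from the pooled labels
    without replacement, holding the feature's call count fixed; the
    empirical one-sided P values carry the +1 correction so they are never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    feat = np.asarray([c == "clonal" for c in feature_calls], dtype=bool)
    pool = np.asarray([c == "clonal" for c in all_calls], dtype=bool)
    n = feat.size
    if n == 0:
        raise ValueError("feature has no calls")
    if pool.size < n:
        raise ValueError("all_calls must contain at least as many calls as the feature")
    n_clonal = int(feat.sum())
    rng = np.random.default_rng(rng_seed)
    # drawing n labels without replacement from the pool = hypergeometric count
    perm_clonal = rng.hypergeometric(
        int(pool.sum()), int(pool.size - pool.sum()), n, size=n_perm
    )
    p_clonal = (1 + int((perm_clonal >= n_clonal).sum())) / (n_perm + 1)
    p_subclonal = (1 + int((perm_clonal <= n_clonal).sum())) / (n_perm + 1)
    return EnrichmentPermResult(
        feature=feature,
        n_clonal=n_clonal,
        n_subclonal=n - n_clonal,
        observed_ratio=n_clonal / n,
        p_clonal=p_clonal,
        p_subclonal=p_subclonal,
    )


def clonal_enrichment_table(
    feature_call_map: Mapping[str, Sequence[str]],
    all_calls: Sequence[str],
    n_perm: int = 10000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`clonal_enrichment_test` per feature and BH-adjust both
    one-sided P families (q_clonal / q_subclonal) across features."""
    results = []
    for i, (feature, calls) in enumerate(sorted(feature_call_map.items())):
        results.append(
            clonal_enrichment_test(
                calls, all_calls, n_perm=n_perm, rng_seed=rng_seed + i, feature=feature
            )
        )
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "n_clonal": [r.n_clonal for r in results],
            "n_subclonal": [r.n_subclonal for r in results],
            "observed_ratio": [r.observed_ratio for r in results],
            "p_clonal": [r.p_clonal for r in results],
            "p_subclonal": [r.p_subclonal for r in results],
        }
    )
    df["q_clonal"] = bh_adjust(df["p_clonal"])
    df["q_subclonal"] = bh_adjust(df["p_subclonal"])
    return df


def temporal_ordering(
    feature_ccfs: Mapping[str, Sequence[float]],
    n_boot: int = 1000,
    rng_seed: int = 0,
    min_carriers: int = 3,
) -> pd.DataFrame:
    """Rank features by mean carrier CCF (high mean CCF = acquired early).

    Features observed in fewer than ``min_carriers`` samples are excluded.
    Bootstrap percentile intervals (2.5/97.5%) are attached to the mean;
    rank tertiles label features early / intermediate / late. Ties in mean
    CCF are broken lexicographically by feature name.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for feature in sorted(feature_ccfs):
        ccfs = np.asarray(feature_ccfs[feature], dtype=float)
        if ccfs.size < min_carriers:
            continue
        boots = rng.choice(ccfs, size=(n_boot, ccfs.size), replace=True).mean(axis=1)
        rows.append(
            (
                feature,
                ccfs.size,
                float(ccfs.mean()),
                float(np.percentile(boots, 2.5)),
                float(np.percentile(boots, 97.5)),
            )
        )
    if not rows:
        raise ValueError("no feature meets the carrier minimum")
    df = pd.DataFrame(
        rows, columns=["feature", "n_carriers", "mean_ccf", "ci_low", "ci_high"]
    )
    # descending mean CCF; lexicographic tie-break is given by the pre-sort
    df = df.sort_values(
        ["mean_ccf", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(df)
    ranks = np.arange(n)
    tertile = np.minimum(ranks * 3 // max(n, 1), 2)
    df["stage"] = np.array(["early", "intermediate", "late"])[tertile]
    return df


def length_weighted_ccf(
    ccfs: Sequence[float], lengths: Sequence[float]
) -> float:
    """Length-weighted mean CCF of the segments composing an arm event."""
    ccfs = np.asarray(ccfs, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if ccfs.size == 0 or lengths.sum() <= 0:
        raise ValueError("need at least one segment with positive length")
    return float((ccfs * lengths).sum() / lengths.sum())
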