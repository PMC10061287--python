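"""Mutational-signature machinery: 96-context spectra, ARD Bayesian NMF
extraction, reference matching, per-mutation attribution, and signature-
activity (MSig) clustering.

The 96 contexts index pyrimidine-strand single-base substitutions
(C>A, C>G, C>T, T>A, T>C, T>G) by their 5' and 3' flanking bases, ordered
A[C>A]A, A[C>A]C, ... T[T>G]T (substitution major, then 5' base, then 3'
base, each alphabetical). Substitutions recorded on the purine strand are
reverse-complemented into this representation.

Signature extraction uses multiplicative-update NMF under the KL (Poisson)
divergence with automatic relevance determination: each component k carries
a relevance scale lambda_k with an exponential prior on its W and H entries;
components whose relevance collapses are pruned, so the number of signatures
is inferred rather than fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AgglomerativeClustering

from .records import MutationRecord, RecordError, revcomp

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CONTEXT_LABELS: List[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


def context_label(ref: str, alt: str, context3: str) -> str:
    """Map an SNV to its pyrimidine-strand 96-context label."""
    if len(context3) != 3 or context3[1] != ref:
        raise RecordError(
            f"context3 {context3!r} middle base does not match ref {ref!r}"
        )
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        context3 = revcomp(context3)
        ref = revcomp(ref)
        alt = revcomp(alt)
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


def context_index(ref: str, alt: str, context3: str) -> int:
    return _CONTEXT_INDEX[context_label(ref, alt, context3)]


def build_spectrum(
    mutations: Iterable[MutationRecord],
    context_fn=None,
) -> pd.DataFrame:
    """96-context mutation spectra, one column per sample.

    Indels are excluded. SNVs must carry ``context3`` or ``context_fn`` must
    supply one from (chrom, pos).
    """
    counts: Dict[str, np.ndarray] = {}
    for mut in mutations:
        if not mut.is_snv:
            continue
        ctx = mut.context3
        if ctx is None:
            if context_fn is None:
                raise RecordError(
                    f"SNV at {mut.chrom}:{mut.pos} lacks context3 and no "
                    "context source was provided"
                )
            ctx = context_fn(mut.chrom, mut.pos)
            if ctx[1] != mut.ref:
                raise RecordError(
                    f"reference context {ctx!r} middle base != ref {mut.ref!r} "
                    f"at {mut.chrom}:{mut.pos}"
                )
        idx = context_index(mut.ref, mut.alt, ctx)
        if mut.sample_id not in counts:
            counts[mut.sample_id] = np.zeros(96, dtype=int)
        counts[mut.sample_id][idx] += 1
    return pd.DataFrame(counts, index=CONTEXT_LABELS).astype(int)


# ------------------------------------------------------------------ ARD-NMF

@dataclass
class SignatureDecomposition:
    """W: 96 x K spectra (columns sum to 1); H: K x N expected counts."""

    W: pd.DataFrame
    H: pd.DataFrame
    relevance: np.ndarray
    K_active: int
    objective: List[float] = field(default_factory=list)


def _ard_nmf_once(
    V: np.ndarray,
    K: int,
    rng: np.random.Generator,
    a: float,
    b: float,
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[float]]:
    F, N = V.shape
    eps = np.finfo(float).tiny
    scale = np.sqrt(V.mean() / K)
    W = scale * (0.5 + rng.random((F, K)))
    H = scale * (0.5 + rng.random((K, N)))
    c_shape = F + N + a + 1.0
    lam = (W.sum(axis=0) + H.sum(axis=1) + b) / c_shape
    trace: List[float] = []

    def objective() -> float:
        WH = W @ H + eps
        kl = float((V * np.log((V + eps) / WH) - V + WH).sum())
        pen = float(((W.sum(axis=0) + H.sum(axis=1) + b) / lam).sum())
        return kl + pen + float(c_shape * np.log(lam).sum())

    prev = objective()
    trace.append(prev)
    for _ in range(max_iter):
        WH = W @ H + eps
        W *= (V / WH) @ H.T / (H.sum(axis=1)[None, :] + (1.0 / lam)[None, :] + eps)
        WH = W @ H + eps
        H *= W.T @ (V / WH) / (W.sum(axis=0)[:, None] + (1.0 / lam)[:, None] + eps)
        lam = (W.sum(axis=0) + H.sum(axis=1) + b) / c_shape
        cur = objective()
        if cur > prev + 1e-6 * abs(prev):  # MM guarantee, numerical slack only
            raise RuntimeError("ARD-NMF objective increased")
        trace.append(cur)
        if abs(prev - cur) <= tol * abs(prev):
            break
        prev = cur
    return W, H, lam, trace


def ardnmf_extract(
    count_matrix,
    K_max: int = 10,
    n_restarts: int = 3,
    tol: float = 1e-8,
    rng_seed: int = 0,
    max_iter: int = 2000,
    prune_fraction: float = 0.01,
    a: float = 10.0,
    b: Optional[float] = None,
) -> SignatureDecomposition:
    """Extract mutational signatures with ARD NMF under KL divergence.

    ``count_matrix`` is 96 x N (contexts x samples), non-negative integers.
    Components whose share of the reconstructed mutation mass falls below
    ``prune_fraction`` are removed; the best of ``n_restarts`` (by final
    objective) is returned. Deterministic given ``rng_seed``.
    """
    if isinstance(count_matrix, pd.DataFrame):
        samples = list(count_matrix.columns)
        V = count_matrix.to_numpy(dtype=float)
    else:
        V = np.asarray(count_matrix, dtype=float)
        samples = [f"S{j}" for j in range(V.shape[1])]
    if V.ndim != 2 or V.shape[0] != 96:
        raise ValueError("count matrix must be 96 x N")
    if V.shape[1] < 2:
        raise ValueError("need at least two samples")
    if np.any(V < 0):
        raise ValueError("counts must be non-negative")
    if V.sum() == 0:
        raise ValueError("count matrix is all zero")
    if b is None:
        # prior scale matched to the per-component data scale
        b = float(np.sqrt(V.mean()))
    best: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray, List[float]]] = None
    root = np.random.default_rng(rng_seed)
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        result = _ard_nmf_once(V, K_max, rng, a=a, b=b, tol=tol, max_iter=max_iter)
        if best is None or result[3][-1] < best[3][-1]:
            best = result
    W, H, lam, trace = best
    mass = W.sum(axis=0) * H.sum(axis=1)
    share = mass / mass.sum()
    keep = np.where(share >= prune_fraction)[0]
    # order retained signatures by decreasing mass for stable naming
    keep = keep[np.argsort(-mass[keep], kind="mergesort")]
    W, H, lam = W[:, keep], H[keep, :], lam[keep]
    col = W.sum(axis=0)
    W = W / col[None, :]
    H = H * col[:, None]
    names = [f"SIG{i + 1}" for i in range(len(keep))]
    return SignatureDecomposition(
        W=pd.DataFrame(W, index=CONTEXT_LABELS, columns=names),
        H=pd.DataFrame(H, index=names, columns=samples),
        relevance=lam,
        K_active=len(keep),
        objective=trace,
    )


# ------------------------------------------------------------------ matching

def cosine_similarity_matrix(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    a = A.to_numpy(dtype=float)
    b = B.to_numpy(dtype=float)
    an = a / np.linalg.norm(a, axis=0, keepdims=True)
    bn = b / np.linalg.norm(b, axis=0, keepdims=True)
    return pd.DataFrame(an.T @ bn, index=A.columns, columns=B.columns)


def match_signatures(
    W: pd.DataFrame,
    reference_spectra: pd.DataFrame,
    cluster: bool = False,
):
    """Match extracted spectra to a reference catalog by cosine similarity.

    Returns ``(assignment, cosine_matrix, pearson_matrix)`` and, when
    ``cluster`` is set, additionally an average-linkage tree of the joint
    signature set (cosine distance), as a scipy linkage matrix.
    """
    if W.shape[0] != reference_spectra.shape[0]:
        raise ValueError("extracted and reference spectra must share 96 rows")
    cos = cosine_similarity_matrix(W, reference_spectra)
    pear = pd.DataFrame(
        np.corrcoef(W.to_numpy().T, reference_spectra.to_numpy().T)[
            : W.shape[1], W.shape[1]:
        ],
        index=W.columns,
        columns=reference_spectra.columns,
    )
    best = cos.idxmax(axis=1)
    assignment = pd.DataFrame(
        {
            "signature": W.columns,
            "best_match": best.values,
            "cosine": [cos.loc[s, best[s]] for s in W.columns],
            "pearson": [pear.loc[s, best[s]] for s in W.columns],
        }
    )
    if not cluster:
        return assignment, cos, pear
    joint = pd.concat([W, reference_spectra], axis=1)
    sim = cosine_similarity_matrix(joint, joint).to_numpy()
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    return assignment, cos, pear, tree


# --------------------------------------------------------------- attribution

def attribute_mutations(
    W: pd.DataFrame,
    H: pd.DataFrame,
    mutation_table: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each SNV to the signature maximising W[context,k] * H[k,sample]
    and aggregate activities within clonal and subclonal subsets.

    ``mutation_table`` needs columns ``sample_id``, ``context`` (96-context
    label), ``clonality``. Ties go to the lowest signature index. Returns a
    long table (sample_id, signature, clonal, subclonal, total).
    """
    missing = set(mutation_table["sample_id"]) - set(H.columns)
    if missing:
        raise ValueError(f"samples missing from activity matrix: {sorted(missing)[:5]}")
    Wm = W.to_numpy(dtype=float)
    sigs = list(W.columns)
    out = {}
    for sample, grp in mutation_table.groupby("sample_id", sort=True):
        h = H[sample].to_numpy(dtype=float)
        ctx_idx = np.array([_CONTEXT_INDEX[c] for c in grp["context"]])
        scores = Wm[ctx_idx, :] * h[None, :]
        assigned = np.argmax(scores, axis=1)  # argmax takes the first maximum
        is_clonal = (grp["clonality"] == "clonal").to_numpy()
        for k, name in enumerate(sigs):
            sel = assigned == k
            out[(sample, name)] = (
                int((sel & is_clonal).sum()),
                int((sel & ~is_clonal).sum()),
            )
    rows = [
        (sample, sig, c, s, c + s) for (sample, sig), (c, s) in sorted(out.items())
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "signature", "clonal", "subclonal", "total"]
    )


def activity_matrix(attribution: pd.DataFrame, which: str = "total") -> pd.DataFrame:
    """Pivot an attribution table to samples x signatures counts."""
    return attribution.pivot_table(
        index="sample_id", columns="signature", values=which, fill_value=0
    )


# ---------------------------------------------------------------- clustering

@dataclass
class MsigClustering:
    labels: pd.Series  # per sample, 1..K
    K_clusters: int
    wss: Dict[int, float]


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def msig_cluster(
    activities: pd.DataFrame,
    K_range: Sequence[int] = tuple(range(2, 9)),
    elbow_fraction: float = 0.10,
) -> MsigClustering:
    """Cluster samples by signature activity.

    Activities (samples x signatures, counts) are transformed per signature
    as log10(count + 1) then z-scored; samples are joined by Ward linkage on
    Euclidean distance. K is the smallest candidate for which adding one
    more cluster no longer improves the total within-cluster sum of squares
    (wss) by more than ``elbow_fraction`` of the total sum of squares
    (wss at K = 1).
    """
    if np.any(activities.to_numpy() < 0):
        raise ValueError("activities must be non-negative")
    K_range = sorted(K_range)
    if activities.shape[0] < max(K_range) + 1:
        raise ValueError("fewer samples than the largest candidate K + 1")
    X = np.log10(activities.to_numpy(dtype=float) + 1.0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    wss: Dict[int, float] = {1: _wss(X, np.zeros(X.shape[0], dtype=int))}
    labels_by_k: Dict[int, np.ndarray] = {}
    for K in [*K_range, max(K_range) + 1]:
        model = AgglomerativeClustering(n_clusters=K, linkage="ward")
        labels_by_k[K] = model.fit_predict(X)
        wss[K] = _wss(X, labels_by_k[K])
    total = wss[1]
    chosen = K_range[-1]
    for K in K_range:
        if total <= 0 or wss[K] <= 0:
            chosen = K
            break
        if (wss[K] - wss[K + 1]) / total < elbow_fraction:
            chosen = K
            break
    labels = pd.Series(
        labels_by_k[chosen] + 1, index=activities.index, name="msig_cluster"
    )
    return MsigClustering(labels=labels, K_clusters=chosen, wss=wss)
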