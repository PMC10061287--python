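"""Intra-tumor heterogeneity metrics.

MATH (mutant-allele tumor heterogeneity) summarises the spread of a tumor's
variant allele fractions: MATH = 100 * MAD / median, with the MAD scaled by
the 1.4826 normal-consistency constant. The Shannon entropy of CCFs measures
how widely a tumor's mutations spread over cancer cell fraction space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class HeterogeneityMetrics:
    sample_id: str
    math: float
    entropy_nats: float
    n_mutations: int


def math_score(vafs: Sequence[float]) -> float:
    """MATH = 100 * MAD / median of the mutant-allele fractions."""
    v = np.asarray(vafs, dtype=float)
    if v.size < 2:
        raise ValueError("MATH requires at least two VAF values")
    if np.any((v <= 0) | (v > 1)):
        raise ValueError("VAFs must lie in (0, 1]")
    med = float(np.median(v))
    if med == 0:
        raise ValueError("median VAF is zero")
    mad = MAD_CONSTANT * float(np.median(np.abs(v - med)))
    return 100.0 * mad / med


def ccf_entropy(ccfs: Sequence[float], n_bins: int = 10) -> float:
    """Shannon entropy (nats) of CCFs binned into ``n_bins`` equal-width bins
    over (0, 1]."""
    c = np.asarray(ccfs, dtype=float)
    if c.size == 0:
        raise ValueError("no CCF values supplied")
    if np.any((c <= 0) | (c > 1)):
        raise ValueError("CCFs must lie in (0, 1]")
    # bin i covers (i/n, (i+1)/n]; ceil maps a CCF to its bin
    idx = np.ceil(c * n_bins).astype(int) - 1
    counts = np.bincount(idx, minlength=n_bins)
    p = counts[counts > 0] / c.size
    return float(-(p * np.log(p)).sum())
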