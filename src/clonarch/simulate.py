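"""Synthetic multi-population tumor cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes in
real cohorts: per-population mutational-signature mixtures over 96
trinucleotide contexts; a clone structure per tumor (one clonal population
at CCF 1 plus 0-3 subclones); purity and sequencing depth; allelic
copy-number segments with planted chromosome/arm/focal events; driver-gene
mutations; and an immune expression matrix with planted subtype shifts.
Populations differ only through their configured parameters, so tests can
attribute every downstream difference to a configured cause.

The read-count model is deliberately simple: mutation multiplicity 1 on a
diploid (1,1) background unless a copy state is configured, so the expected
VAF of a mutation at cancer cell fraction c in a tumor of purity rho is
rho * c / 2 and alt counts are Binomial(depth, VAF). Reference spectra are
synthetic stand-ins for a catalog: sparse, well-separated probability
vectors over the 96 contexts.

Everything is deterministic given ``CohortSpec.rng_seed``; the three
generator stages (mutations, segments, expression) use independent
substreams over a shared sample table, so they can be called in any order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import ArmModel, ClinicalRecord, MutationRecord, SegmentRecord
from .signatures import BASES, CONTEXT_LABELS, revcomp

# ------------------------------------------------------------ building blocks

_CHROM_LENGTHS_MB = {str(i): 250 - 8 * (i - 1) for i in range(1, 23)}
_ACROCENTRIC = {"13", "14", "15", "21", "22"}


def default_arm_model() -> ArmModel:
    """A deterministic 22-autosome arm model (1-based coordinates, Mb-scale
    synthetic lengths; acrocentric chromosomes carry only a q arm)."""
    arms: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for chrom, mb in _CHROM_LENGTHS_MB.items():
        length = mb * 1_000_000
        p_len = int(length * 0.4)
        if chrom in _ACROCENTRIC:
            arms[chrom] = {"q": (1, length)}
        else:
            arms[chrom] = {"p": (1, p_len), "q": (p_len + 1, length)}
    return ArmModel(arms=arms)


def synthetic_reference_spectra(
    n_signatures: int = 5, n_peaks: int = 8, rng_seed: int = 20240901
) -> pd.DataFrame:
    """Synthetic stand-in reference catalog: ``n_signatures`` sparse,
    well-separated 96-context probability vectors (columns sum to 1)."""
    rng = np.random.default_rng(rng_seed)
    cols = {}
    taken: set = set()
    for k in range(n_signatures):
        # disjoint dominant peaks keep pairwise cosine low
        free = [i for i in range(96) if i not in taken]
        peaks = rng.choice(free, size=n_peaks, replace=False)
        taken.update(peaks.tolist())
        w = np.full(96, 0.1 / 96)
        w[peaks] += rng.dirichlet(np.full(n_peaks, 1.5)) * 0.9
        cols[f"REF{k + 1}"] = w / w.sum()
    return pd.DataFrame(cols, index=CONTEXT_LABELS)


def default_immune_gene_sets(
    cell_types: Sequence[str] = (
        "CD8 T cells",
        "Th17 cells",
        "Th2 cells",
        "Macrophages",
        "NK cells",
        "B cells",
    ),
    genes_per_set: int = 25,
) -> Dict[str, List[str]]:
    """Synthetic immune cell-type gene sets (disjoint marker genes)."""
    sets = {}
    for t, cell_type in enumerate(cell_types):
        tag = re.sub(r"\W+", "", cell_type).upper()
        sets[cell_type] = [f"{tag}_{i:03d}" for i in range(genes_per_set)]
    return sets


# -------------------------------------------------------- cohort parameters

_FEATURE_RE = re.compile(r"^(amp|del)\((\d+)([pq]?)\)$")


def parse_feature(feature: str) -> Tuple[str, str, Optional[str]]:
    """Parse 'del(9p)' / 'amp(20)' into (sign, chrom, arm-or-None)."""
    m = _FEATURE_RE.match(feature)
    if not m:
        raise ValueError(f"cannot parse SCNA feature {feature!r}")
    sign = "amplification" if m.group(1) == "amp" else "deletion"
    return sign, m.group(2), m.group(3) or None


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults describe a mixed-ancestry
    bladder-tumor-like study."""

    populations: Dict[str, int] = field(
        default_factory=lambda: {"Asian": 60, "Black": 20, "White": 120}
    )
    reference_spectra: pd.DataFrame = field(
        default_factory=synthetic_reference_spectra
    )
    # per-population mixture weights over reference_spectra columns
    exposures: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "Asian": {"REF1": 0.3, "REF2": 0.15, "REF3": 0.15, "REF4": 0.25, "REF5": 0.15},
            "Black": {"REF1": 0.55, "REF2": 0.45},
            "White": {"REF1": 0.45, "REF2": 0.3, "REF3": 0.25},
        }
    )
    mutations_per_sample: float = 100.0  # Poisson mean
    # per-sample signature mixtures are Dirichlet draws centred on the
    # population mixture; the concentration controls tumor-to-tumor
    # variability in signature activity (lower = more variable), which is
    # what makes the mixture identifiable from cohort spectra at all
    exposure_concentration: float = 1.0
    subclonal_fraction: float = 0.3  # P(mutation belongs to a subclone)
    n_subclones_range: Tuple[int, int] = (1, 3)
    subclone_ccf_range: Tuple[float, float] = (0.1, 0.8)
    purity_beta: Tuple[float, float] = (8.0, 4.0)  # Beta params, mean 2/3
    depth_mean: float = 100.0  # Poisson mean, clamped below at depth_min
    depth_min: int = 10
    copy_state: Tuple[int, int] = (1, 1)  # local (major, minor) at SNV loci
    silent_fraction: float = 0.2
    indel_fraction: float = 0.03
    n_background_genes: int = 2000
    driver_genes: Dict[str, float] = field(
        default_factory=lambda: {
            "TP53": 0.45, "FGFR3": 0.2, "HRAS": 0.1, "ARID1A": 0.25,
            "KDM6A": 0.25, "ATM": 0.12, "RB1": 0.15, "CREBBP": 0.12,
            "NFE2L2": 0.08, "ELF3": 0.1,
        }
    )
    driver_clonal_prob: float = 0.9
    # arm-level SCNA features: feature -> (P(clonal event), P(subclonal event))
    arm_event_probs: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "del(9p)": (0.3, 0.1), "del(9q)": (0.25, 0.1), "del(17p)": (0.25, 0.12),
            "del(8p)": (0.2, 0.12), "amp(20)": (0.15, 0.1), "del(11p)": (0.18, 0.1),
            "amp(1q)": (0.15, 0.08), "del(21q)": (0.1, 0.08),
        }
    )
    focal_event_probs: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    # planted subtypes: name -> cohort fraction
    subtype_fractions: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.5, "B": 0.5}
    )
    # per-subtype overrides of driver rates / arm rates (merged over the base)
    subtype_driver_rates: Dict[str, Dict[str, float]] = field(default_factory=dict)
    subtype_arm_rates: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=dict
    )
    # per-subtype immune shifts: subtype -> cell type -> additive log-scale shift
    immune_shifts: Dict[str, Dict[str, float]] = field(default_factory=dict)
    n_expression_background: int = 500
    expression_sigma: float = 0.5
    rng_seed: int = 0

    def n_total(self) -> int:
        return sum(self.populations.values())


@dataclass
class GroundTruth:
    """Per-record generating truth for a synthetic cohort."""

    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    mutations: pd.DataFrame = field(default_factory=pd.DataFrame)
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            samples=self.samples if len(self.samples) else other.samples,
            mutations=self.mutations if len(self.mutations) else other.mutations,
            segments=self.segments if len(self.segments) else other.segments,
        )


# -------------------------------------------------------------- sample table

def _substream(spec: CohortSpec, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.rng_seed, offset]))


def sample_table(spec: CohortSpec) -> pd.DataFrame:
    """Shared per-sample metadata: population, purity, subtype, subclone
    CCFs. Identical across generator stages for a fixed seed."""
    rng = _substream(spec, 0)
    rows = []
    subtype_names = list(spec.subtype_fractions)
    weights = np.array([spec.subtype_fractions[s] for s in subtype_names], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("subtype fractions must sum to a positive value")
    weights = weights / weights.sum()
    i = 0
    for pop, n in spec.populations.items():
        for _ in range(n):
            i += 1
            purity = float(rng.beta(*spec.purity_beta))
            purity = float(np.clip(purity, 0.05, 1.0))
            n_sub = int(rng.integers(spec.n_subclones_range[0], spec.n_subclones_range[1] + 1))
            sub_ccfs = np.sort(rng.uniform(*spec.subclone_ccf_range, size=n_sub))[::-1]
            subtype = subtype_names[rng.choice(len(subtype_names), p=weights)] if subtype_names else ""
            rows.append(
                (
                    f"S{i:04d}",
                    pop,
                    purity,
                    subtype,
                    n_sub,
                    ",".join(f"{c:.4f}" for c in sub_ccfs),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "population", "purity", "subtype", "n_subclones", "subclone_ccfs"],
    )


def clinical_records(spec: CohortSpec) -> List[ClinicalRecord]:
    """Clinical table consistent with the sample table (stage / invasiveness
    / follow-up drawn from simple priors)."""
    rng = _substream(spec, 4)
    records = []
    for row in sample_table(spec).itertuples(index=False):
        mibc = bool(rng.random() < 0.7)
        stage = rng.choice(["T2N0M0", "T3N0M0", "T3N1M0"]) if mibc else rng.choice(["TaN0M0", "T1N0M0"])
        followup = float(np.round(rng.uniform(3, 80), 1))
        met: Optional[float] = None
        if mibc and rng.random() < 0.25:
            met = float(np.round(rng.uniform(0, min(followup, 24)), 1))
        records.append(
            ClinicalRecord(
                sample_id=row.sample_id,
                race=row.population,
                stage=str(stage),
                invasiveness="MIBC" if mibc else "NMIBC",
                purity=row.purity,
                followup_months=followup,
                metastasis_time_months=met,
            )
        )
    return records


# ------------------------------------------------------------------ mutations

_SUB_FROM_CONTEXT = [
    (label, label[2], label[4], label[0] + label[2] + label[6])
    for label in CONTEXT_LABELS
]  # (label, ref, alt, context3) on the pyrimidine strand


def _draw_clone_ccf(rng, row, subclonal_fraction: float) -> float:
    sub_ccfs = [float(x) for x in row.subclone_ccfs.split(",") if x]
    if sub_ccfs and rng.random() < subclonal_fraction:
        return float(rng.choice(sub_ccfs))
    return 1.0


def generate_mutations(
    spec: CohortSpec,
) -> Tuple[List[MutationRecord], GroundTruth]:
    """Generate SNVs (and a small indel fraction) for every sample.

    Each SNV draws its generating signature from the sample's population
    mixture and its 96-context from that signature's spectrum; half of the
    time the variant is placed on the purine strand so that strand folding is
    exercised. Alt counts are Binomial(depth, purity * m * ccf / D) with the
    configured copy state.
    """
    rng = _substream(spec, 1)
    table = sample_table(spec)
    ref = spec.reference_spectra
    sig_names = list(ref.columns)
    records: List[MutationRecord] = []
    truth_rows = []
    major, minor = spec.copy_state
    denom_tumor = major + minor
    for row in table.itertuples(index=False):
        mixture = spec.exposures.get(row.population, {})
        w = np.array([mixture.get(s, 0.0) for s in sig_names], dtype=float)
        n_mut = int(rng.poisson(spec.mutations_per_sample))
        if n_mut > 0 and w.sum() <= 0:
            raise ValueError(
                f"population {row.population} exposure weights sum to zero"
            )
        if w.sum() > 0:
            active = w > 0
            alpha = spec.exposure_concentration * int(active.sum()) * w / w.sum()
            w = w.astype(float)
            w[active] = rng.dirichlet(alpha[active])
        gene_pool_size = spec.n_background_genes
        muts = []
        for _ in range(n_mut):
            gene = f"GENE{int(rng.integers(gene_pool_size)):04d}"
            muts.append((gene, None))
        # driver mutations on top of the background
        rates = dict(spec.driver_genes)
        rates.update(spec.subtype_driver_rates.get(row.subtype, {}))
        for gene, rate in sorted(rates.items()):
            if rng.random() < rate:
                muts.append((gene, "driver"))
        for gene, kind in muts:
            ccf = (
                1.0
                if kind == "driver" and rng.random() < spec.driver_clonal_prob
                else _draw_clone_ccf(rng, row, spec.subclonal_fraction)
            )
            depth = max(int(rng.poisson(spec.depth_mean)), spec.depth_min)
            u = rng.random()
            is_indel = kind is None and u < spec.indel_fraction
            if is_indel:
                vclass = "indel"
                ref_allele, alt_allele, context3 = "A", "AT", None
                sig = None
            else:
                vclass = (
                    "silent"
                    if kind is None and u < spec.indel_fraction + spec.silent_fraction
                    else "nonsilent_snv"
                )
                k = int(rng.choice(len(sig_names), p=w / w.sum()))
                sig = sig_names[k]
                ctx_idx = int(rng.choice(96, p=ref[sig].to_numpy()))
                _, r, a, c3 = _SUB_FROM_CONTEXT[ctx_idx]
                if rng.random() < 0.5:  # record on the purine strand
                    r, a, c3 = revcomp(r), revcomp(a), revcomp(c3)
                ref_allele, alt_allele, context3 = r, a, c3
            f = row.purity * 1.0 * ccf / (
                row.purity * denom_tumor + (1 - row.purity) * 2.0
            )
            alt = int(rng.binomial(depth, f))
            chrom = str(int(rng.integers(1, 23)))
            pos = int(rng.integers(1, 10**8))
            records.append(
                MutationRecord(
                    sample_id=row.sample_id,
                    chrom=chrom,
                    pos=pos,
                    ref=ref_allele,
                    alt=alt_allele,
                    gene=gene,
                    variant_class=vclass,
                    alt_count=alt,
                    depth=depth,
                    context3=context3,
                )
            )
            truth_rows.append(
                (
                    row.sample_id, chrom, pos, gene, vclass, sig, ccf,
                    ccf >= 0.95, kind == "driver",
                )
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id", "chrom", "pos", "gene", "variant_class",
            "signature", "clone_ccf", "clonal", "is_driver",
        ],
    )
    return records, GroundTruth(samples=table, mutations=truth)


# ------------------------------------------------------------------- segments

def generate_segments(
    spec: CohortSpec, arms: ArmModel
) -> Tuple[List[SegmentRecord], GroundTruth]:
    """Generate allelic copy-number segments with planted events.

    Planted arm events cover 60-95% of the arm (> 50% rule satisfied);
    chromosome features alter every modeled arm with the same sign; focal
    features cover 5-30%. The rest of the genome is (1,1).
    """
    rng = _substream(spec, 2)
    table = sample_table(spec)
    for feature in list(spec.arm_event_probs) + list(spec.focal_event_probs):
        sign, chrom, arm = parse_feature(feature)
        if chrom not in arms.arms:
            raise ValueError(f"feature {feature}: chromosome {chrom} not in arm model")
        if arm is not None and arm not in arms.arms[chrom]:
            raise ValueError(f"feature {feature}: arm {arm} not in arm model")
    records: List[SegmentRecord] = []
    truth_rows = []
    for row in table.itertuples(index=False):
        arm_rates = dict(spec.arm_event_probs)
        arm_rates.update(spec.subtype_arm_rates.get(row.subtype, {}))
        planted: Dict[Tuple[str, str], Tuple[str, float, float, str]] = {}
        # (chrom, arm) -> (sign, ccf, coverage, scope)
        for feature, (p_clonal, p_subclonal) in sorted(arm_rates.items()):
            sign, chrom, arm = parse_feature(feature)
            u = rng.random()
            if u < p_clonal:
                ccf = 1.0
            elif u < p_clonal + p_subclonal:
                ccf = float(rng.uniform(*spec.subclone_ccf_range))
            else:
                continue
            targets = [arm] if arm is not None else arms.arm_names(chrom)
            scope = "arm" if arm is not None else "chromosome"
            coverage = float(rng.uniform(0.6, 0.95))
            for t in targets:
                planted.setdefault((chrom, t), (sign, ccf, coverage, scope))
        focal: Dict[Tuple[str, str], Tuple[str, float, float]] = {}
        for feature, (p_clonal, p_subclonal) in sorted(spec.focal_event_probs.items()):
            sign, chrom, arm = parse_feature(feature)
            if arm is None:
                raise ValueError(f"focal feature {feature} must name an arm")
            u = rng.random()
            if u < p_clonal:
                ccf = 1.0
            elif u < p_clonal + p_subclonal:
                ccf = float(rng.uniform(*spec.subclone_ccf_range))
            else:
                continue
            if (chrom, arm) not in planted:
                focal[(chrom, arm)] = (sign, ccf, float(rng.uniform(0.05, 0.3)))
        for chrom in arms.arms:
            for arm in arms.arm_names(chrom):
                start, end = arms.arm_span(chrom, arm)
                if (chrom, arm) in planted:
                    sign, ccf, coverage, scope = planted[(chrom, arm)]
                    alt_len = int((end - start + 1) * coverage)
                elif (chrom, arm) in focal:
                    sign, ccf, coverage = focal[(chrom, arm)]
                    alt_len = int((end - start + 1) * coverage)
                    scope = "focal"
                else:
                    records.append(
                        SegmentRecord(row.sample_id, chrom, start, end, 1, 1)
                    )
                    truth_rows.append(
                        (row.sample_id, chrom, start, end, np.nan, None, None)
                    )
                    continue
                cn = (2, 1) if sign == "amplification" else (1, 0)
                alt_end = start + alt_len - 1
                records.append(
                    SegmentRecord(row.sample_id, chrom, start, alt_end, *cn)
                )
                truth_rows.append(
                    (row.sample_id, chrom, start, alt_end, ccf, sign, scope)
                )
                if alt_end < end:
                    records.append(
                        SegmentRecord(row.sample_id, chrom, alt_end + 1, end, 1, 1)
                    )
                    truth_rows.append(
                        (row.sample_id, chrom, alt_end + 1, end, np.nan, None, None)
                    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "start", "end", "ccf", "sign", "scope"],
    )
    return records, GroundTruth(samples=table, segments=truth)


# ----------------------------------------------------------------- expression

def generate_expression(
    spec: CohortSpec, gene_sets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Log-normal expression matrix (genes x samples) with planted per-
    subtype shifts of the named immune cell-type sets."""
    if not gene_sets or any(len(g) == 0 for g in gene_sets.values()):
        raise ValueError("gene sets must be non-empty")
    rng = _substream(spec, 3)
    table = sample_table(spec)
    genes: List[str] = []
    for name in gene_sets:
        genes.extend(gene_sets[name])
    genes = list(dict.fromkeys(genes))
    genes += [f"BG{i:04d}" for i in range(spec.n_expression_background)]
    # reject contradictory shift requests (one gene pushed both ways)
    for subtype, shifts in spec.immune_shifts.items():
        direction: Dict[str, float] = {}
        for cell_type, shift in shifts.items():
            if cell_type not in gene_sets:
                raise ValueError(f"immune shift names unknown set {cell_type!r}")
            for gene in gene_sets[cell_type]:
                prev = direction.get(gene)
                if prev is not None and prev * shift < 0:
                    raise ValueError(
                        f"gene {gene} receives conflicting up/down shifts in "
                        f"subtype {subtype}"
                    )
                direction[gene] = shift
    base_mu = rng.normal(3.0, 1.0, size=len(genes))
    gene_idx = {g: i for i, g in enumerate(genes)}
    X = np.empty((len(genes), len(table)))
    for j, row in enumerate(table.itertuples(index=False)):
        mu = base_mu.copy()
        for cell_type, shift in spec.immune_shifts.get(row.subtype, {}).items():
            for gene in gene_sets[cell_type]:
                mu[gene_idx[gene]] += shift
        X[:, j] = np.exp(mu + rng.normal(0, spec.expression_sigma, size=len(genes)))
    return pd.DataFrame(X, index=genes, columns=list(table["sample_id"]))


# ------------------------------------------------------------------- assembly

@dataclass
class SyntheticCohort:
    spec: CohortSpec
    mutations: List[MutationRecord]
    segments: List[SegmentRecord]
    clinical: List[ClinicalRecord]
    arms: ArmModel
    expression: pd.DataFrame
    gene_sets: Dict[str, List[str]]
    truth: GroundTruth


def generate_cohort(
    spec: CohortSpec,
    arms: Optional[ArmModel] = None,
    gene_sets: Optional[Mapping[str, Sequence[str]]] = None,
) -> SyntheticCohort:
    """Run all generator stages and assemble a complete cohort."""
    arms = arms or default_arm_model()
    gene_sets = dict(gene_sets or default_immune_gene_sets())
    mutations, truth_m = generate_mutations(spec)
    segments, truth_s = generate_segments(spec, arms)
    expression = generate_expression(spec, gene_sets)
    clinical = clinical_records(spec)
    return SyntheticCohort(
        spec=spec,
        mutations=mutations,
        segments=segments,
        clinical=clinical,
        arms=arms,
        expression=expression,
        gene_sets=dict(gene_sets),
        truth=truth_m.merge(truth_s),
    )
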