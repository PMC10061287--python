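"""Readers and writers for the cohort's tabular formats, plus clinical
labeling and gene-panel filtering.

All files are plain TSV with declared headers:

* mutations (MAF-like): Tumor_Sample_Barcode, Chromosome, Start_Position,
  Reference_Allele, Tumor_Seq_Allele2, Hugo_Symbol, Variant_Classification,
  t_alt_count, t_depth, Context3
* segments (SEG-like):  Sample, Chromosome, Start, End, Major_CN, Minor_CN
  (1-based inclusive coordinates)
* clinical:             Sample, Race, Stage, Invasiveness, Purity,
  Followup_Months, Metastasis_Time_Months (may be blank)
* arms (BED-like TSV):  chrom, arm, start, end (1-based inclusive)

Unknown samples in the mutation or segment files are rejected against the
clinical table.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .records import (
    ArmModel,
    ClinicalRecord,
    FormatError,
    MutationRecord,
    RecordError,
    SegmentRecord,
    check_referential_integrity,
)

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Hugo_Symbol",
    "Variant_Classification",
    "t_alt_count",
    "t_depth",
    "Context3",
]
SEGMENT_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Major_CN", "Minor_CN"]
CLINICAL_COLUMNS = [
    "Sample",
    "Race",
    "Stage",
    "Invasiveness",
    "Purity",
    "Followup_Months",
    "Metastasis_Time_Months",
]
ARM_COLUMNS = ["chrom", "arm", "start", "end"]


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _record_error(path, idx: int, exc: Exception) -> RecordError:
    # +2: one for the header row, one for 1-based line numbering
    return RecordError(f"{path} line {idx + 2}: {exc}")


def read_mutations(path) -> List[MutationRecord]:
    df = _read_tsv(path, MUTATION_COLUMNS)
    out: List[MutationRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        ctx = getattr(row, "Context3")
        if ctx is None or (isinstance(ctx, float) and math.isnan(ctx)) or ctx == "":
            ctx = None
        try:
            out.append(
                MutationRecord(
                    sample_id=row.Tumor_Sample_Barcode,
                    chrom=row.Chromosome,
                    pos=int(row.Start_Position),
                    ref=row.Reference_Allele,
                    alt=row.Tumor_Seq_Allele2,
                    gene=row.Hugo_Symbol,
                    variant_class=row.Variant_Classification,
                    alt_count=int(row.t_alt_count),
                    depth=int(row.t_depth),
                    context3=ctx,
                )
            )
        except (RecordError, ValueError) as exc:
            raise _record_error(path, idx, exc) from exc
    return out


def read_segments(path) -> List[SegmentRecord]:
    df = _read_tsv(path, SEGMENT_COLUMNS)
    out: List[SegmentRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                SegmentRecord(
                    sample_id=row.Sample,
                    chrom=row.Chromosome,
                    start=int(row.Start),
                    end=int(row.End),
                    major=int(row.Major_CN),
                    minor=int(row.Minor_CN),
                )
            )
        except (RecordError, ValueError) as exc:
            raise _record_error(path, idx, exc) from exc
    _check_non_overlap(out, path)
    return out


def _check_non_overlap(segments: Sequence[SegmentRecord], path) -> None:
    by_key: Dict[Tuple[str, str], List[SegmentRecord]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise RecordError(
                    f"{path}: overlapping segments for sample {sample} on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def read_clinical(path) -> List[ClinicalRecord]:
    df = _read_tsv(path, CLINICAL_COLUMNS)
    out: List[ClinicalRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        met = row.Metastasis_Time_Months
        if met is None or met == "" or (isinstance(met, float) and math.isnan(met)):
            met_val: Optional[float] = None
        else:
            met_val = float(met)
        try:
            out.append(
                ClinicalRecord(
                    sample_id=row.Sample,
                    race=row.Race,
                    stage=row.Stage,
                    invasiveness=row.Invasiveness,
                    purity=float(row.Purity),
                    followup_months=float(row.Followup_Months),
                    metastasis_time_months=met_val,
                )
            )
        except (RecordError, ValueError) as exc:
            raise _record_error(path, idx, exc) from exc
    return out


def read_arms(path) -> ArmModel:
    df = _read_tsv(path, ARM_COLUMNS)
    arms: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            arms.setdefault(row.chrom, {})[row.arm] = (int(row.start), int(row.end))
        except ValueError as exc:
            raise _record_error(path, idx, exc) from exc
    return ArmModel(arms=arms)


def read_cohort(
    mutations_path, segments_path, clinical_path, arms_path
) -> Tuple[List[MutationRecord], List[SegmentRecord], List[ClinicalRecord], ArmModel]:
    """Load the four cohort tables with invariants and referential integrity
    enforced."""
    clinical = read_clinical(clinical_path)
    known = [c.sample_id for c in clinical]
    mutations = read_mutations(mutations_path)
    segments = read_segments(segments_path)
    check_referential_integrity((m.sample_id for m in mutations), known, "mutations")
    check_referential_integrity((s.sample_id for s in segments), known, "segments")
    arms = read_arms(arms_path)
    return mutations, segments, clinical, arms


# ---------------------------------------------------------------- writers

def write_mutations(records: Iterable[MutationRecord], path) -> None:
    rows = [
        (
            m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.gene, m.variant_class,
            m.alt_count, m.depth, m.context3 if m.context3 is not None else "",
        )
        for m in records
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_segments(records: Iterable[SegmentRecord], path) -> None:
    rows = [(s.sample_id, s.chrom, s.start, s.end, s.major, s.minor) for s in records]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    rows = [
        (
            c.sample_id, c.race, c.stage, c.invasiveness, c.purity,
            c.followup_months,
            "" if c.metastasis_time_months is None else c.metastasis_time_months,
        )
        for c in records
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def write_arms(model: ArmModel, path) -> None:
    rows = [
        (chrom, arm, s, e)
        for chrom, arm_map in model.arms.items()
        for arm, (s, e) in arm_map.items()
    ]
    pd.DataFrame(rows, columns=ARM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Gene-by-sample expression matrix; first column holds gene names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expression matrix has no sample columns")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="Gene")


def read_gene_sets(path) -> Dict[str, List[str]]:
    """GMT format: set name, description, then member genes, tab-separated."""
    sets: Dict[str, List[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: GMT line with fewer than 3 fields: {line!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gene_sets(sets: Dict[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_reference_spectra(path) -> pd.DataFrame:
    """Reference signature matrix: 96 context rows x named signature columns,
    each column a probability distribution."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise FormatError(f"{path}: expected 96 context rows, found {df.shape[0]}")
    return df


# ------------------------------------------------------- labeling / filters

def label_metastatic(clinical: ClinicalRecord, horizon_months: float = 12.0) -> str:
    """Metastasis labeling rule.

    A patient is ``metastatic`` if metastatic disease appeared at biopsy or
    within the horizon (default one year) after it; ``non_metastatic`` if no
    metastasis was seen and follow-up lasted at least the horizon; otherwise
    ``unlabeled`` (insufficient follow-up to rule metastasis out).
    """
    met = clinical.metastasis_time_months
    if met is not None and met < 0:
        raise RecordError("negative metastasis time")
    if met is not None and met <= horizon_months:
        return "metastatic"
    if met is None and clinical.followup_months >= horizon_months:
        return "non_metastatic"
    return "unlabeled"


def filter_gene_panel(
    candidate_genes: Sequence[str],
    expression_matrix: pd.DataFrame,
    census_list: Iterable[str],
    expressed_fraction: float = 0.75,
    min_counts: int = 3,
) -> List[str]:
    """Keep candidate genes that are expressed (>= ``min_counts`` raw counts)
    in strictly more than ``expressed_fraction`` of samples AND appear in the
    cancer-gene census list. Genes absent from the expression matrix fail the
    filter and are logged."""
    census: Set[str] = set(census_list)
    kept: List[str] = []
    n_samples = expression_matrix.shape[1]
    for gene in candidate_genes:
        if gene not in census:
            continue
        if gene not in expression_matrix.index:
            logger.warning("gene %s absent from expression matrix; dropped", gene)
            continue
        frac = (expression_matrix.loc[gene] >= min_counts).sum() / n_samples
        if frac > expressed_fraction:
            kept.append(gene)
    return kept
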