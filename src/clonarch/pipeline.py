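"""End-to-end orchestration: synthetic generation, stage execution, and
reproducible TSV outputs.

A run directory is populated stage by stage; every stage reads only TSVs
(its own inputs or earlier stages' outputs), so any stage can be re-run in
isolation against an existing directory. All randomness derives from the
config seed; re-running with the same config and seed reproduces every
output byte for byte.

Stage order: inputs -> clonality -> heterogeneity / signatures / scna ->
enrichment (clonal + signature) -> subtyping -> immune.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .clonality import (
    ccf_posteriors_batch,
    clonal_enrichment_table,
    cohort_clonality_summary,
    length_weighted_ccf,
    temporal_ordering,
)
from .enrichment import mutation_matrix, select_test_genes, signature_enrichment_table
from .heterogeneity import ccf_entropy, math_score
from .records import ArmModel
from .scna import classify_segments, frequent_arm_events, score_levels
from .signatures import (
    activity_matrix,
    ardnmf_extract,
    attribute_mutations,
    build_spectrum,
    context_label,
    match_signatures,
    msig_cluster,
)
from .simulate import CohortSpec, generate_cohort, synthetic_reference_spectra
from .ssgsea import compare_immune, ssgsea_matrix
from .subtyping import build_ccf_matrix, contrast_clusters, name_clusters, nmf_lee

logger = logging.getLogger(__name__)

STAGES = (
    "inputs",
    "clonality",
    "heterogeneity",
    "signatures",
    "scna",
    "clonal_enrichment",
    "signature_enrichment",
    "subtyping",
    "immune",
)


@dataclass
class Thresholds:
    """Every analysis threshold in one auditable place (the defaults are the
    study profile)."""

    clonal_ccf: float = 0.95
    clonal_prob: float = 0.5
    arm_fraction: float = 0.5
    arm_event_freq: float = 0.30
    gene_freq: float = 0.05
    q_significant: float = 0.1
    n_perm: int = 10000
    k_subtypes: int = 2
    k_max_signatures: int = 10
    nmf_restarts: int = 3
    min_gene_calls: int = 5

    def validate(self) -> None:
        for name in ("clonal_ccf", "clonal_prob", "arm_fraction",
                     "arm_event_freq", "gene_freq", "q_significant"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"threshold {name}={v} outside (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.k_subtypes < 2:
            raise ValueError("k_subtypes must be >= 2")


@dataclass
class PipelineConfig:
    outdir: str = "clonarch_run"
    rng_seed: int = 0
    synthetic: Dict = field(default_factory=dict)  # CohortSpec overrides
    inputs: Dict[str, str] = field(default_factory=dict)  # pre-existing TSVs
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: Sequence[str] = STAGES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(thresholds=thr, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.thresholds.validate()
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "outdir": self.outdir,
                "rng_seed": self.rng_seed,
                "synthetic": self.synthetic,
                "inputs": self.inputs,
                "thresholds": dataclasses.asdict(self.thresholds),
                "stages": list(self.stages),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


class PipelineRun:
    """Stage executor over a run directory."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.thr = config.thresholds

    # ------------------------------------------------------------ inputs

    def stage_inputs(self) -> None:
        cfg = self.config
        if cfg.inputs:
            mutations, segments, clinical, arms = cio.read_cohort(
                cfg.inputs["mutations"], cfg.inputs["segments"],
                cfg.inputs["clinical"], cfg.inputs["arms"],
            )
            cio.write_mutations(mutations, self.out / "mutations.tsv")
            cio.write_segments(segments, self.out / "segments.tsv")
            cio.write_clinical(clinical, self.out / "clinical.tsv")
            cio.write_arms(arms, self.out / "arms.tsv")
            for key, dest in (
                ("expression", "expression.tsv"),
                ("gene_sets", "gene_sets.gmt"),
                ("reference_spectra", "reference_spectra.tsv"),
                ("segment_ccf", "segment_ccf.tsv"),
            ):
                if key in cfg.inputs:
                    (self.out / dest).write_text(Path(cfg.inputs[key]).read_text())
            return
        spec_kwargs = dict(cfg.synthetic)
        spec_kwargs.setdefault("rng_seed", cfg.rng_seed)
        spec = CohortSpec(**spec_kwargs)
        cohort = generate_cohort(spec)
        cio.write_mutations(cohort.mutations, self.out / "mutations.tsv")
        cio.write_segments(cohort.segments, self.out / "segments.tsv")
        cio.write_clinical(cohort.clinical, self.out / "clinical.tsv")
        cio.write_arms(cohort.arms, self.out / "arms.tsv")
        cio.write_expression(cohort.expression, self.out / "expression.tsv")
        cio.write_gene_sets(cohort.gene_sets, self.out / "gene_sets.gmt")
        spec.reference_spectra.to_csv(
            self.out / "reference_spectra.tsv", sep="\t", index_label="Context"
        )
        seg_ccf = cohort.truth.segments[
            ["sample_id", "chrom", "start", "end", "ccf"]
        ].dropna(subset=["ccf"])
        _write(seg_ccf, self.out / "segment_ccf.tsv")
        _write(cohort.truth.mutations, self.out / "truth_mutations.tsv")
        _write(cohort.truth.samples, self.out / "truth_samples.tsv")

    # -------------------------------------------------------------- loads

    def _load_cohort(self):
        return cio.read_cohort(
            self.out / "mutations.tsv", self.out / "segments.tsv",
            self.out / "clinical.tsv", self.out / "arms.tsv",
        )

    def _purity(self) -> Dict[str, float]:
        return {c.sample_id: c.purity for c in cio.read_clinical(self.out / "clinical.tsv")}

    def _segment_ccf(self) -> Optional[pd.DataFrame]:
        path = self.out / "segment_ccf.tsv"
        if not path.exists():
            return None
        return pd.read_csv(path, sep="\t")

    # ----------------------------------------------------------- clonality

    def stage_clonality(self) -> None:
        mutations, segments, clinical, arms = self._load_cohort()
        purity = {c.sample_id: c.purity for c in clinical}
        # local copy state: covering segment, else (1,1)
        seg_lookup: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, List]] = {}
        by_key: Dict[Tuple[str, str], List] = {}
        for seg in segments:
            by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
        for key, segs in by_key.items():
            segs.sort(key=lambda s: s.start)
            seg_lookup[key] = (
                np.array([s.start for s in segs]),
                np.array([s.end for s in segs]),
                segs,
            )
        rows = []
        for m in mutations:
            major, minor = 1, 1
            entry = seg_lookup.get((m.sample_id, m.chrom))
            if entry is not None:
                starts, ends, segs = entry
                i = int(np.searchsorted(starts, m.pos, side="right")) - 1
                if i >= 0 and m.pos <= ends[i]:
                    major, minor = max(segs[i].major, 1), segs[i].minor
            rows.append(
                (
                    m.sample_id, m.chrom, m.pos, m.gene, m.variant_class,
                    max(m.alt_count, 0), m.depth, purity[m.sample_id], major, minor,
                )
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "sample_id", "chrom", "pos", "gene", "variant_class",
                "alt_count", "depth", "purity", "major", "minor",
            ],
        )
        post = ccf_posteriors_batch(
            df["alt_count"], df["depth"], df["purity"], df["major"], df["minor"]
        )
        df = pd.concat([df, post], axis=1)
        df["context"] = [
            context_label(m.ref, m.alt, m.context3) if m.is_snv else ""
            for m in mutations
        ]
        _write(df, self.out / "clonality_mutations.tsv")
        df["event_class"] = np.where(df["variant_class"] == "indel", "indel", "snv")
        calls = df[["event_class", "clonality"]]
        seg_ccf = self._segment_ccf()
        if seg_ccf is not None and len(seg_ccf):
            scna = pd.DataFrame(
                {
                    "event_class": "scna",
                    "clonality": np.where(
                        seg_ccf["ccf"] >= self.thr.clonal_ccf, "clonal", "subclonal"
                    ),
                }
            )
            calls = pd.concat([calls, scna], ignore_index=True)
        _write(cohort_clonality_summary(calls), self.out / "clonality_summary.tsv")

    # ------------------------------------------------------- heterogeneity

    def stage_heterogeneity(self) -> None:
        df = pd.read_csv(self.out / "clonality_mutations.tsv", sep="\t")
        snv = df[df["variant_class"] != "indel"]
        rows = []
        for sample, grp in snv.groupby("sample_id", sort=True):
            vafs = (grp["alt_count"] / grp["depth"]).clip(lower=1e-9, upper=1.0)
            rows.append(
                (
                    sample,
                    math_score(vafs) if len(vafs) >= 2 else np.nan,
                    ccf_entropy(grp["ccf_map"]),
                    len(grp),
                )
            )
        _write(
            pd.DataFrame(rows, columns=["sample_id", "math", "entropy_nats", "n_mutations"]),
            self.out / "heterogeneity.tsv",
        )

    # ---------------------------------------------------------- signatures

    def stage_signatures(self) -> None:
        df = pd.read_csv(self.out / "clonality_mutations.tsv", sep="\t")
        snv = df[df["variant_class"] != "indel"].copy()
        spectra = (
            snv.groupby(["context", "sample_id"]).size().unstack(fill_value=0)
        )
        from .signatures import CONTEXT_LABELS

        spectra = spectra.reindex(CONTEXT_LABELS, fill_value=0)
        decomp = ardnmf_extract(
            spectra,
            K_max=self.thr.k_max_signatures,
            n_restarts=self.thr.nmf_restarts,
            rng_seed=self.config.rng_seed + 11,
        )
        decomp.W.to_csv(self.out / "signature_spectra.tsv", sep="\t", index_label="Context")
        decomp.H.to_csv(self.out / "signature_activities_raw.tsv", sep="\t", index_label="Signature")
        ref_path = self.out / "reference_spectra.tsv"
        if ref_path.exists():
            ref = cio.read_reference_spectra(ref_path)
            assignment, cos, _ = match_signatures(decomp.W, ref)
            _write(assignment, self.out / "signature_matches.tsv")
            cos.to_csv(self.out / "signature_cosine.tsv", sep="\t", index_label="Signature")
        attr = attribute_mutations(
            decomp.W,
            decomp.H,
            snv.rename(columns={"clonality": "clonality"})[
                ["sample_id", "context", "clonality"]
            ],
        )
        _write(attr, self.out / "signature_attribution.tsv")
        act = activity_matrix(attr, "total")
        clustering = msig_cluster(act)
        labels = clustering.labels.rename("msig_cluster").rename_axis("sample_id")
        _write(labels.reset_index(), self.out / "msig_clusters.tsv")
        wss = pd.DataFrame(
            sorted(clustering.wss.items()), columns=["K", "wss"]
        )
        _write(wss, self.out / "msig_wss.tsv")

    # ---------------------------------------------------------------- scna

    def stage_scna(self) -> None:
        _, segments, clinical, arms = self._load_cohort()
        seg_ccf = self._segment_ccf()
        ccf_map: Dict[Tuple, float] = {}
        if seg_ccf is not None:
            for r in seg_ccf.itertuples(index=False):
                ccf_map[(r.sample_id, str(r.chrom), r.start, r.end)] = r.ccf
        by_sample: Dict[str, List] = {}
        for seg in segments:
            by_sample.setdefault(seg.sample_id, []).append(seg)
        all_samples = [c.sample_id for c in clinical]
        for s in all_samples:
            by_sample.setdefault(s, [])
        event_rows = []
        events_by_sample = {}
        for sample in sorted(by_sample):
            segs = by_sample[sample]
            ccfs = [
                ccf_map.get((sample, s.chrom, s.start, s.end), np.nan) for s in segs
            ]
            use_ccfs = ccfs if seg_ccf is not None else None
            if use_ccfs is not None:
                use_ccfs = [1.0 if np.isnan(c) else c for c in use_ccfs]
            events, _ = classify_segments(
                segs, arms, segment_ccfs=use_ccfs, clonal_ccf=self.thr.clonal_ccf
            )
            events_by_sample[sample] = events
            for ev in events:
                event_rows.append(
                    (
                        sample, ev.scope, ev.chrom, ev.arm or "", ev.sign,
                        ev.feature, np.nan if ev.ccf is None else ev.ccf,
                        ev.clonality,
                    )
                )
        _write(
            pd.DataFrame(
                event_rows,
                columns=[
                    "sample_id", "scope", "chrom", "arm", "sign",
                    "feature", "ccf", "clonality",
                ],
            ),
            self.out / "scna_events.tsv",
        )
        scores = score_levels(
            {s: by_sample[s] for s in by_sample if by_sample[s]}, arms
        )
        scores.index.name = "sample_id"
        _write(scores.reset_index(), self.out / "scna_scores.tsv")
        freq = frequent_arm_events(
            events_by_sample, min_freq=self.thr.arm_event_freq, arms=arms
        )
        _write(freq, self.out / "frequent_arm_events.tsv")

    # -------------------------------------------------- clonal enrichment

    def stage_clonal_enrichment(self) -> None:
        muts = pd.read_csv(self.out / "clonality_mutations.tsv", sep="\t")
        nonsilent = muts[muts["variant_class"] != "silent"]
        feature_calls: Dict[str, List[str]] = {}
        counts = nonsilent.groupby("gene").size()
        for gene in counts.index[counts >= self.thr.min_gene_calls]:
            feature_calls[gene] = list(nonsilent.loc[nonsilent["gene"] == gene, "clonality"])
        events = pd.read_csv(self.out / "scna_events.tsv", sep="\t")
        arm_ev = events[
            (events["scope"].isin(["arm", "chromosome"]))
            & (events["clonality"] != "unknown")
        ]
        for feature, grp in arm_ev.groupby("feature"):
            if len(grp) >= self.thr.min_gene_calls:
                feature_calls[feature] = list(grp["clonality"])
        pool = list(nonsilent["clonality"]) + list(arm_ev["clonality"])
        table = clonal_enrichment_table(
            feature_calls, pool,
            n_perm=self.thr.n_perm, rng_seed=self.config.rng_seed + 23,
        )
        _write(table, self.out / "clonal_enrichment.tsv")
        # temporal ordering over the same features, from carrier CCFs
        ccfs = {
            gene: list(nonsilent.loc[nonsilent["gene"] == gene, "ccf_map"])
            for gene in feature_calls
            if gene in set(nonsilent["gene"])
        }
        for feature, grp in arm_ev.groupby("feature"):
            if feature in feature_calls:
                ccfs[feature] = list(grp["ccf"].dropna())
        order = temporal_ordering(
            {k: v for k, v in ccfs.items() if len(v) >= 3},
            rng_seed=self.config.rng_seed + 24,
        )
        _write(order, self.out / "temporal_order.tsv")

    # ----------------------------------------------- signature enrichment

    def stage_signature_enrichment(self) -> None:
        mutations, _, clinical, _ = self._load_cohort()
        samples = [c.sample_id for c in clinical]
        M = mutation_matrix(mutations, samples)
        genes = select_test_genes(M, min_freq=self.thr.gene_freq)
        attr = pd.read_csv(self.out / "signature_attribution.tsv", sep="\t")
        act = activity_matrix(attr, "total").reindex(samples, fill_value=0)
        table = signature_enrichment_table(
            M.loc[:, samples], act, genes=genes,
            n_perm=self.thr.n_perm, rng_seed=self.config.rng_seed + 31,
        )
        _write(table, self.out / "signature_enrichment.tsv")

    # ------------------------------------------------------------ subtyping

    def stage_subtyping(self) -> None:
        muts = pd.read_csv(self.out / "clonality_mutations.tsv", sep="\t")
        clinical = cio.read_clinical(self.out / "clinical.tsv")
        samples = [c.sample_id for c in clinical]
        nonsilent = muts[muts["variant_class"] == "nonsilent_snv"]
        counts = nonsilent.groupby("gene").size()
        driver_genes = set(counts.index[counts >= self.thr.min_gene_calls])
        gene_calls = nonsilent[nonsilent["gene"].isin(driver_genes)][
            ["sample_id", "gene", "ccf_map"]
        ].rename(columns={"ccf_map": "ccf"})
        events = pd.read_csv(self.out / "scna_events.tsv", sep="\t")
        freq = pd.read_csv(self.out / "frequent_arm_events.tsv", sep="\t")
        freq_features = {
            f"{'amp' if r.sign == 'amplification' else 'del'}({r.chrom}{r.arm})"
            for r in freq.itertuples(index=False)
        }
        arm_ev = events[events["scope"].isin(["arm", "chromosome"])].copy()
        rows = []
        for r in arm_ev.itertuples(index=False):
            if r.scope == "chromosome":
                feats = [
                    f"{'amp' if r.sign == 'amplification' else 'del'}({r.chrom}{a})"
                    for a in ("p", "q")
                ]
            else:
                feats = [r.feature]
            for f in feats:
                if f in freq_features:
                    rows.append((r.sample_id, f, 1.0 if pd.isna(r.ccf) else r.ccf))
        arm_calls = pd.DataFrame(rows, columns=["sample_id", "feature", "ccf"])
        arm_calls = (
            arm_calls.groupby(["sample_id", "feature"], as_index=False)["ccf"].max()
        )
        X = build_ccf_matrix(gene_calls, arm_calls, samples)
        solution = nmf_lee(
            X, K=self.thr.k_subtypes,
            rng_seed=self.config.rng_seed + 41,
        )
        scores = pd.read_csv(self.out / "scna_scores.tsv", sep="\t").set_index("sample_id")
        labels = name_clusters(solution.labels, scores["ArmL"])
        X.to_csv(self.out / "ccf_feature_matrix.tsv", sep="\t", index_label="Feature")
        _write(labels.rename_axis("sample_id").reset_index(), self.out / "subtype_labels.tsv")
        solution.basis.to_csv(self.out / "subtype_basis.tsv", sep="\t", index_label="Feature")
        solution.coefficients.to_csv(self.out / "subtype_coefficients.tsv", sep="\t", index_label="Factor")
        carriers = (X > 0).astype(int)
        het = pd.read_csv(self.out / "heterogeneity.tsv", sep="\t").set_index("sample_id")
        metrics = het[["math", "entropy_nats"]].join(
            scores[["ChromL", "ArmL", "FocalL", "total_normalized"]]
        )
        binary, cont = contrast_clusters(labels, carriers, metrics)
        _write(binary, self.out / "subtype_contrasts_binary.tsv")
        _write(cont, self.out / "subtype_contrasts_metrics.tsv")

    # --------------------------------------------------------------- immune

    def stage_immune(self) -> None:
        expr = cio.read_expression(self.out / "expression.tsv")
        gene_sets = cio.read_gene_sets(self.out / "gene_sets.gmt")
        scores = ssgsea_matrix(expr, gene_sets)
        scores.to_csv(self.out / "immune_scores.tsv", sep="\t", index_label="CellType")
        labels_path = self.out / "subtype_labels.tsv"
        if labels_path.exists():
            labels = pd.read_csv(labels_path, sep="\t").set_index("sample_id")["subtype"]
            comparison = compare_immune(scores, labels)
            _write(comparison, self.out / "immune_contrasts.tsv")

    # ------------------------------------------------------------- dispatch

    def run(self, stages: Optional[Sequence[str]] = None) -> Path:
        stages = list(stages or self.config.stages)
        manifest = {
            "version": __version__,
            "rng_seed": self.config.rng_seed,
            "config_hash": self.config.config_hash(),
            "thresholds": dataclasses.asdict(self.thr),
            "stages": [],
        }
        try:
            for stage in STAGES:
                if stage not in stages:
                    continue
                logger.info("running stage %s", stage)
                getattr(self, f"stage_{stage}")()
                manifest["stages"].append(stage)
        except Exception:
            manifest["failed"] = True
            (self.out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        (self.out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return self.out


def run_pipeline(config: PipelineConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Execute the configured stages; returns the output directory."""
    return PipelineRun(config).run(stages)
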