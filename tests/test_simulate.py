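"""Synthetic-cohort generator: determinism, spectrum fidelity, VAF model,
planted segments and expression shifts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clonarch.scna import classify_segments
from clonarch.signatures import build_spectrum
from clonarch.simulate import (
    CohortSpec,
    default_arm_model,
    default_immune_gene_sets,
    generate_expression,
    generate_mutations,
    generate_segments,
    parse_feature,
    synthetic_reference_spectra,
)
from clonarch.ssgsea import ssgsea_matrix


def _single_sig_spec(n=10, muts=1000.0, seed=0):
    ref = synthetic_reference_spectra(2)
    return CohortSpec(
        populations={"White": n},
        reference_spectra=ref,
        exposures={"White": {"REF1": 1.0}},
        mutations_per_sample=muts,
        silent_fraction=0.0,
        indel_fraction=0.0,
        driver_genes={},
        arm_event_probs={},
        rng_seed=seed,
    )


class TestMutations:
    def test_deterministic_given_seed(self):
        spec = _single_sig_spec(n=4, muts=50.0, seed=3)
        a, ta = generate_mutations(spec)
        b, tb = generate_mutations(spec)
        assert a == b
        pd.testing.assert_frame_equal(ta.mutations, tb.mutations)

    def test_single_signature_spectrum_matches_generator(self):
        spec = _single_sig_spec(n=10, muts=1000.0, seed=1)
        muts, _ = generate_mutations(spec)
        spectrum = build_spectrum(muts).sum(axis=1)
        empirical = spectrum / spectrum.sum()
        target = spec.reference_spectra["REF1"]
        tv = 0.5 * float(np.abs(empirical - target).sum())
        assert tv < 0.05

    def test_expected_vaf_from_purity_and_ccf(self):
        spec = _single_sig_spec(n=20, muts=300.0, seed=2)
        spec.purity_beta = (1e6, 1e6)  # purity pinned at 0.5
        spec.subclonal_fraction = 0.0  # all clonal, CCF = 1
        muts, _ = generate_mutations(spec)
        vafs = np.array([m.alt_count / m.depth for m in muts])
        assert vafs.mean() == pytest.approx(0.25, abs=0.005)

    def test_zero_samples_empty_output(self):
        spec = _single_sig_spec(n=0)
        spec.populations = {}
        muts, truth = generate_mutations(spec)
        assert muts == [] and len(truth.mutations) == 0

    def test_zero_exposure_with_positive_count_rejected(self):
        spec = _single_sig_spec(n=2, muts=50.0)
        spec.exposures = {"White": {"REF1": 0.0}}
        with pytest.raises(ValueError, match="zero"):
            generate_mutations(spec)

    def test_ground_truth_clonal_flag_matches_ccf_threshold(self):
        spec = _single_sig_spec(n=10, muts=100.0, seed=4)
        spec.subclonal_fraction = 0.4
        _, truth = generate_mutations(spec)
        t = truth.mutations
        assert ((t["clone_ccf"] >= 0.95) == t["clonal"]).all()
        planted = 1 - t["clonal"].mean()
        assert 0.2 < planted < 0.5  # near the configured 0.4 times subclone availability

    def test_depth_floor_respected(self):
        spec = _single_sig_spec(n=5, muts=100.0, seed=5)
        spec.depth_mean = 12.0
        muts, _ = generate_mutations(spec)
        assert min(m.depth for m in muts) >= spec.depth_min


class TestSegments:
    def test_planted_arm_deletion_classified_downstream(self, arm_model):
        spec = _single_sig_spec(n=30, seed=6)
        spec.arm_event_probs = {"del(9p)": (1.0, 0.0)}
        segs, truth = generate_segments(spec, arm_model)
        by_sample = {}
        for s in segs:
            by_sample.setdefault(s.sample_id, []).append(s)
        for sample, ss in by_sample.items():
            events, _ = classify_segments(ss, arm_model)
            assert any(
                e.scope == "arm" and e.chrom == "9" and e.arm == "p"
                and e.sign == "deletion"
                for e in events
            )

    def test_no_planted_events_all_normal(self, arm_model):
        spec = _single_sig_spec(n=5, seed=7)
        segs, _ = generate_segments(spec, arm_model)
        assert all((s.major, s.minor) == (1, 1) for s in segs)

    def test_chromosome_amplification_alters_both_arms_same_sign(self, arm_model):
        spec = _single_sig_spec(n=10, seed=8)
        spec.arm_event_probs = {"amp(20)": (1.0, 0.0)}
        segs, _ = generate_segments(spec, arm_model)
        for sample in {s.sample_id for s in segs}:
            ss = [s for s in segs if s.sample_id == sample]
            events, _ = classify_segments(ss, arm_model)
            assert any(
                e.scope == "chromosome" and e.chrom == "20"
                and e.sign == "amplification"
                for e in events
            )

    def test_unknown_arm_rejected(self, arm_model):
        spec = _single_sig_spec(n=2, seed=9)
        spec.arm_event_probs = {"del(13p)": (1.0, 0.0)}  # 13 is acrocentric
        with pytest.raises(ValueError):
            generate_segments(spec, arm_model)

    def test_focal_events_stay_below_arm_threshold(self, arm_model):
        spec = _single_sig_spec(n=15, seed=10)
        spec.focal_event_probs = {"del(5q)": (1.0, 0.0)}
        segs, _ = generate_segments(spec, arm_model)
        for sample in {s.sample_id for s in segs}:
            ss = [s for s in segs if s.sample_id == sample]
            events, _ = classify_segments(ss, arm_model)
            focal = [e for e in events if e.sign == "deletion"]
            assert focal and all(e.scope == "focal" for e in focal)

    def test_parse_feature(self):
        assert parse_feature("del(9p)") == ("deletion", "9", "p")
        assert parse_feature("amp(20)") == ("amplification", "20", None)
        with pytest.raises(ValueError):
            parse_feature("gain(9p)")


class TestExpression:
    def test_planted_shift_separates_subtypes(self):
        sets = default_immune_gene_sets()
        spec = _single_sig_spec(n=60, seed=11)
        spec.immune_shifts = {"B": {"CD8 T cells": 1.5}}
        expr = generate_expression(spec, sets)
        from clonarch.simulate import sample_table

        table = sample_table(spec).set_index("sample_id")
        scores = ssgsea_matrix(expr, {"CD8 T cells": sets["CD8 T cells"]})
        a = scores.loc["CD8 T cells", table.index[table["subtype"] == "A"]]
        b = scores.loc["CD8 T cells", table.index[table["subtype"] == "B"]]
        assert sps.mannwhitneyu(b, a, alternative="greater").pvalue < 1e-4

    def test_null_shift_is_calibrated(self):
        sets = {"set1": default_immune_gene_sets()["CD8 T cells"]}
        pvals = []
        for seed in range(12):
            spec = _single_sig_spec(n=24, seed=100 + seed)
            expr = generate_expression(spec, sets)
            from clonarch.simulate import sample_table

            table = sample_table(spec).set_index("sample_id")
            scores = ssgsea_matrix(expr, sets)
            a = scores.loc["set1", table.index[table["subtype"] == "A"]]
            b = scores.loc["set1", table.index[table["subtype"] == "B"]]
            pvals.append(sps.mannwhitneyu(a, b).pvalue)
        # no planted shift: P values should not pile up near zero
        assert min(pvals) > 0.001 or sorted(pvals)[1] > 0.05
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_gene_set_rejected(self):
        spec = _single_sig_spec(n=2)
        with pytest.raises(ValueError):
            generate_expression(spec, {"empty": []})

    def test_conflicting_shifts_rejected(self):
        sets = {"up": ["gA", "gB"], "down": ["gB", "gC"]}
        spec = _single_sig_spec(n=2)
        spec.immune_shifts = {"A": {"up": 1.0, "down": -1.0}}
        with pytest.raises(ValueError, match="conflicting"):
            generate_expression(spec, sets)

    def test_deterministic_given_seed(self):
        sets = default_immune_gene_sets()
        spec = _single_sig_spec(n=5, seed=13)
        pd.testing.assert_frame_equal(
            generate_expression(spec, sets), generate_expression(spec, sets)
        )
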