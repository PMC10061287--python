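"""CCF posterior, clonality rule, enrichment permutation, temporal order."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom, hypergeom

from clonarch.clonality import (
    CCF_GRID,
    CcfPosterior,
    ccf_posterior,
    ccf_posteriors_batch,
    classify_clonality,
    clonal_enrichment_table,
    clonal_enrichment_test,
    cohort_clonality_summary,
    length_weighted_ccf,
    temporal_ordering,
)


class TestCcfPosterior:
    def test_balanced_het_in_pure_tumor_is_clonal(self):
        post = ccf_posterior(50, 100, 1.0, 1, 1)
        assert post.ccf_map == pytest.approx(1.00)
        assert post.clonality == "clonal"

    def test_map_matches_grid_enumeration_oracle(self):
        # oracle: direct binomial likelihood over the 100-point grid
        f = 0.5 * 1 * CCF_GRID / (0.5 * 2 + 0.5 * 2)
        lik = binom.pmf(10, 100, f)
        expected = CCF_GRID[np.argmax(lik)]
        post = ccf_posterior(10, 100, 0.5, 1, 1)
        assert post.ccf_map == pytest.approx(expected) == pytest.approx(0.40)

    def test_zero_alt_reads_pin_to_grid_minimum(self):
        post = ccf_posterior(0, 100, 0.5, 1, 1)
        assert post.ccf_map == pytest.approx(0.01)
        assert post.clonality == "subclonal"

    def test_posterior_mass_conserved(self):
        for alt in (0, 3, 47, 100):
            post = ccf_posterior(alt, 100, 0.7, 2, 1)
            assert post.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_map_nondecreasing_in_alt_count(self):
        maps = [ccf_posterior(a, 80, 0.6, 1, 1).ccf_map for a in range(0, 81, 4)]
        assert all(b >= a for a, b in zip(maps, maps[1:]))

    @pytest.mark.parametrize(
        "kwargs", [dict(depth=0), dict(purity=0.0), dict(major=0)]
    )
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(alt_count=5, depth=20, purity=0.5, major=1, minor=1)
        base.update(kwargs)
        if "depth" in kwargs:
            base["alt_count"] = 0
        with pytest.raises(ValueError):
            ccf_posterior(**base)

    def test_batch_agrees_with_scalar_path(self):
        rng = np.random.default_rng(0)
        depth = rng.integers(20, 200, size=50)
        alt = rng.binomial(depth, 0.3)
        purity = rng.uniform(0.3, 1.0, size=50)
        batch = ccf_posteriors_batch(
            alt, depth, purity, np.full(50, 2), np.ones(50)
        )
        for i in range(0, 50, 7):
            post = ccf_posterior(int(alt[i]), int(depth[i]), float(purity[i]), 2, 1)
            assert batch.loc[i, "ccf_map"] == pytest.approx(post.ccf_map)
            assert batch.loc[i, "p_ge_095"] == pytest.approx(post.p_ge_095, abs=1e-9)
            assert batch.loc[i, "clonality"] == post.clonality


class TestClonalityRule:
    def _post(self, p95):
        grid = CCF_GRID
        post = np.zeros(100)
        post[-6:] = p95 / 6  # mass at >= 0.95
        post[:94] = (1 - p95) / 94
        return CcfPosterior("e", grid, post / post.sum(), 1.0, p95, "clonal" if p95 > 0.5 else "subclonal")

    def test_strictly_greater_than_half(self):
        assert classify_clonality(self._post(0.6)) == "clonal"
        assert classify_clonality(self._post(0.5)) == "subclonal"
        assert classify_clonality(self._post(0.0)) == "subclonal"


class TestCohortSummary:
    def test_fraction_arithmetic(self):
        calls = pd.DataFrame(
            {
                "event_class": ["snv"] * 10 + ["indel"] * 4,
                "clonality": ["clonal"] * 9 + ["subclonal"] + ["clonal"] * 4,
            }
        )
        out = cohort_clonality_summary(calls).set_index("event_class")
        assert out.loc["snv", "subclonal_fraction"] == pytest.approx(0.10)
        assert out.loc["indel", "subclonal_fraction"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cohort_clonality_summary(pd.DataFrame(columns=["event_class", "clonality"]))


class TestClonalEnrichment:
    def test_all_clonal_feature_is_extreme(self):
        pool = ["clonal"] * 500 + ["subclonal"] * 500
        res = clonal_enrichment_test(["clonal"] * 10, pool, n_perm=10000, rng_seed=1)
        assert res.p_clonal <= 0.01
        assert res.p_subclonal > 0.5

    def test_single_call_feature_is_uninformative(self):
        pool = ["clonal"] * 500 + ["subclonal"] * 500
        res = clonal_enrichment_test(["clonal"], pool, n_perm=10000, rng_seed=2)
        assert res.p_clonal == pytest.approx(0.5, abs=0.03)

    def test_feature_matching_cohort_ratio_is_null(self):
        pool = ["clonal"] * 600 + ["subclonal"] * 400
        res = clonal_enrichment_test(
            ["clonal"] * 6 + ["subclonal"] * 4, pool, n_perm=10000, rng_seed=3
        )
        assert 0.3 < res.p_clonal < 0.85

    def test_matches_exact_hypergeometric_tail(self):
        # oracle: the permutation null with fixed count n drawn from the pool
        # is Hypergeometric(N, K, n)
        pool = ["clonal"] * 30 + ["subclonal"] * 20
        feature = ["clonal"] * 5 + ["subclonal"] * 1
        n_perm = 20000
        res = clonal_enrichment_test(feature, pool, n_perm=n_perm, rng_seed=4)
        exact = hypergeom.sf(4, 50, 30, 6)  # P(X >= 5)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_clonal - exact) < 3 * se + 2 / n_perm

    def test_pvalues_never_zero_and_table_has_q(self):
        pool = ["clonal"] * 50 + ["subclonal"] * 50
        table = clonal_enrichment_table(
            {"g1": ["clonal"] * 20, "g2": ["subclonal"] * 20},
            pool,
            n_perm=500,
            rng_seed=5,
        )
        assert (table["p_clonal"] > 0).all() and (table["p_subclonal"] > 0).all()
        assert {"q_clonal", "q_subclonal"} <= set(table.columns)

    def test_rejects_bad_nperm(self):
        with pytest.raises(ValueError):
            clonal_enrichment_test(["clonal"], ["clonal"], n_perm=0)


class TestTemporalOrdering:
    def test_orders_by_mean_ccf_and_breaks_ties_by_name(self):
        table = {
            "early_gene": [1.0, 1.0, 1.0],
            "late_gene": [0.3, 0.3, 0.3],
            "tie_b": [0.5, 0.5, 0.5],
            "tie_a": [0.5, 0.5, 0.5],
        }
        out = temporal_ordering(table, n_boot=100, rng_seed=0)
        order = list(out["feature"])
        assert order[0] == "early_gene" and order[-1] == "late_gene"
        assert order.index("tie_a") < order.index("tie_b")
        assert out.set_index("feature").loc["early_gene", "stage"] == "early"
        assert out.set_index("feature").loc["late_gene", "stage"] == "late"

    def test_carrier_minimum_enforced(self):
        out = temporal_ordering(
            {"keep": [1.0, 0.9, 0.8], "drop": [1.0]}, n_boot=50, rng_seed=0
        )
        assert list(out["feature"]) == ["keep"]
        with pytest.raises(ValueError):
            temporal_ordering({"drop": [1.0]}, n_boot=50, rng_seed=0)


def test_length_weighted_ccf():
    assert length_weighted_ccf([1.0, 0.5], [3, 1]) == pytest.approx(0.875)
    with pytest.raises(ValueError):
        length_weighted_ccf([], [])


@given(
    alt=st.integers(0, 60),
    depth=st.integers(60, 200),
    purity=st.floats(0.2, 1.0),
)
def test_posterior_always_normalised(alt, depth, purity):
    post = ccf_posterior(alt, depth, purity, 1, 1)
    assert post.posterior.sum() == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= post.p_ge_095 <= 1.0
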