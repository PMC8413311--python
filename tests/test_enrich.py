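"""Enrichment statistics against exhaustive / closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mprakit import (ContingencyTable2x2, binomial_concordance,
                     concordance_quadrants, eqtl_qq, fisher_2x2,
                     locus_eqtl_adjust, odds_ratio_ci, overlap_intervals,
                     snp_to_interval)


def hypergeom_two_sided(a, b, c, d):
    """Exhaustive enumeration oracle: sum hypergeometric probabilities of all
    tables with the same margins that are no more likely than observed."""
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    obs = stats.hypergeom.pmf(a, n, n1, k)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        p = stats.hypergeom.pmf(x, n, n1, k)
        if p <= obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_equal_proportions(self):
        res = fisher_2x2([[10, 10], [10, 10]])
        assert res["odds_ratio"] == 1.0 and res["pvalue"] == 1.0

    @pytest.mark.parametrize("table", [
        (3, 7, 5, 5), (1, 9, 9, 1), (20, 5, 5, 20), (0, 10, 10, 0),
        (12, 3, 7, 8), (2, 2, 2, 2), (50, 20, 10, 40),
    ])
    def test_matches_exhaustive_enumeration(self, table):
        a, b, c, d = table
        res = fisher_2x2([[a, b], [c, d]])
        oracle = hypergeom_two_sided(a, b, c, d)
        assert res["pvalue"] == pytest.approx(oracle, rel=1e-12)

    def test_two_sided_at_least_one_sided(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 30, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            two = fisher_2x2([[a, b], [c, d]])["pvalue"]
            less = stats.fisher_exact([[a, b], [c, d]], alternative="less")[1]
            greater = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert two >= min(less, greater) - 1e-12

    def test_invariant_under_row_and_column_swap(self):
        res1 = fisher_2x2([[3, 7], [5, 5]])
        res2 = fisher_2x2([[5, 5], [7, 3]])  # swap rows then columns
        assert res1["pvalue"] == pytest.approx(res2["pvalue"], rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2([[0, 0], [5, 5]])

    def test_category_comparison_from_printed_fractions(self):
        """The active-fraction comparison between SNP categories built from
        printed numerator/denominator pairs runs and is highly significant
        (the printed p is reported, not asserted: the original test's
        element/allele units are ambiguous)."""
        res = fisher_2x2([[824, 1910 - 824], [707, 2218 - 707]])
        assert res["pvalue"] < 1e-10
        assert res["odds_ratio"] > 1


class TestOddsRatioCI:
    def test_unit_or_spans_one(self):
        res = odds_ratio_ci([[10, 10], [10, 10]])
        assert res["odds_ratio"] == 1.0
        assert res["lower"] < 1 < res["upper"]

    def test_woolf_formula_oracle(self):
        a, b, c, d = 20, 5, 5, 20
        res = odds_ratio_ci([[a, b], [c, d]])
        log_or = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(0.975)
        assert res["lower"] == pytest.approx(np.exp(log_or - z * se), abs=1e-9)
        assert res["upper"] == pytest.approx(np.exp(log_or + z * se), abs=1e-9)

    def test_ordering_property(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = rng.integers(0, 40, size=4)
            if (t[0] + t[1] == 0) or (t[2] + t[3] == 0) or (t[0] + t[2] == 0) or (t[1] + t[3] == 0):
                continue
            res = odds_ratio_ci(t.reshape(2, 2))
            assert res["lower"] <= res["odds_ratio"] <= res["upper"]

    def test_zero_cell_haldane_flagged(self):
        res = odds_ratio_ci([[0, 10], [5, 5]])
        assert res["haldane"] and np.isfinite(res["lower"])


class TestBinomialConcordance:
    def test_direction_concordance_across_conditions(self):
        # cross-condition direction concordance of allelic effects
        assert binomial_concordance(332, 338) == pytest.approx(7.2e-90, rel=0.05)

    def test_caqtl_direction_concordance(self):
        # agreement between reporter skew and chromatin accessibility
        assert binomial_concordance(246, 297) == pytest.approx(8.6e-32, rel=0.05)

    def test_symmetry_and_balanced_case(self):
        assert binomial_concordance(5, 10) == 1.0
        for k in range(11):
            assert binomial_concordance(k, 10) == pytest.approx(
                binomial_concordance(10 - k, 10), rel=1e-12)

    def test_matches_pmf_summation_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            obs = stats.binom.pmf(k, n, 0.5)
            x = np.arange(n + 1)
            oracle = stats.binom.pmf(x, n, 0.5)[
                stats.binom.pmf(x, n, 0.5) <= obs * (1 + 1e-12)].sum()
            assert binomial_concordance(k, n) == pytest.approx(min(oracle, 1.0),
                                                               rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_concordance(5, 4)


class TestQuadrants:
    def test_manual_tally(self):
        df = pd.DataFrame({"mpra": [1, -1, 1, -1, 1, -1],
                           "external": [1, -1, -1, 1, 1, -1]})
        res = concordance_quadrants(df)
        assert res["Q1"] == 2 and res["Q3"] == 2 and res["Q2"] == 1 and res["Q4"] == 1
        assert res["concordant_fraction"] == pytest.approx(4 / 6)

    def test_empty_input(self):
        res = concordance_quadrants(pd.DataFrame({"mpra": [], "external": []}))
        assert res["total"] == 0 and np.isnan(res["concordant_fraction"])

    def test_negation_symmetry(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"mpra": rng.normal(size=30),
                           "external": rng.normal(size=30)})
        r1 = concordance_quadrants(df)
        r2 = concordance_quadrants(-df)
        assert r1["concordant_fraction"] == r2["concordant_fraction"]

    def test_zeros_excluded_and_counted(self):
        df = pd.DataFrame({"mpra": [0.0, 1.0], "external": [1.0, 1.0]})
        res = concordance_quadrants(df)
        assert res["n_zero_excluded"] == 1 and res["total"] == 1


class TestOverlap:
    def test_half_open_semantics(self):
        elements = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                 "start": [100, 100], "end": [300, 300]})
        ann = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "start": [250, 300], "end": [400, 400],
                            "label": ["SINE", "LINE"]})
        out = overlap_intervals(elements.iloc[[0]], ann.iloc[[0]])
        assert out["overlap"].iloc[0]
        out2 = overlap_intervals(elements.iloc[[0]], ann.iloc[[1]])
        assert not out2["overlap"].iloc[0]  # adjacency is not overlap

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(8)
        n_el, n_ann = 300, 120
        elements = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2", "chr3"], n_el),
            "start": rng.integers(0, 5000, n_el)})
        elements["end"] = elements["start"] + rng.integers(1, 300, n_el)
        ann = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2", "chr3"], n_ann),
            "start": rng.integers(0, 5000, n_ann)})
        ann["end"] = ann["start"] + rng.integers(1, 200, n_ann)
        ann["label"] = rng.choice(["LINE", "LTR", "SINE"], n_ann)
        out = overlap_intervals(elements, ann)
        for i, e in elements.iterrows():
            brute = ((ann["chrom"] == e["chrom"]) & (ann["start"] < e["end"])
                     & (e["start"] < ann["end"])).any()
            assert out.loc[i, "overlap"] == brute

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            overlap_intervals(pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [10]}),
                              pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5]}))

    def test_snp_coordinate_conversion(self):
        assert snp_to_interval(1) == (0, 1)
        assert snp_to_interval(100) == (99, 100)
        with pytest.raises(ValueError):
            snp_to_interval(0)


class TestEqtlQQ:
    def test_uniform_sample_tracks_diagonal(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=1000)
        qq = eqtl_qq(p)
        # KS-style bound on -log10 quantile agreement in the bulk
        bulk = qq[qq["expected"] < 2]
        assert np.abs(bulk["observed"] - bulk["expected"]).max() < 0.35

    def test_enriched_group_lifts_top_decile(self):
        rng = np.random.default_rng(10)
        enriched = np.concatenate([rng.beta(0.2, 1, 500), rng.uniform(size=500)])
        qq = eqtl_qq(enriched)
        top = qq.iloc[:100]  # rank order: smallest p first
        assert (top["observed"] > top["expected"]).mean() > 0.9

    def test_shape_and_monotonicity(self):
        p = np.array([0.5, 0.01, 0.2, 1.0])
        qq = eqtl_qq(p)
        assert len(qq) == 4
        # observed is nonincreasing in rank order (best p first)
        assert (np.diff(qq["observed"]) <= 0).all()
        assert (np.diff(qq["expected"]) <= 0).all()

    def test_zero_p_clipped_and_flagged(self):
        qq = eqtl_qq(np.array([0.0, 0.5]))
        assert qq["clipped"].any()
        assert np.isfinite(qq["observed"]).all()


class TestLocusAdjust:
    def test_single_gene(self):
        out = locus_eqtl_adjust(pd.DataFrame({"gene": ["g1"], "pvalue": [0.004]}))
        assert out["p_adjusted"].iloc[0] == pytest.approx(0.004)
        assert out["significant"].iloc[0]

    def test_bonferroni_arithmetic(self):
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(10)],
                              "pvalue": [0.0005] + [0.5] * 9})
        out = locus_eqtl_adjust(genes).set_index("gene")
        assert out.at["g0", "p_adjusted"] == pytest.approx(0.005)
        assert out.at["g0", "significant"]
        genes2 = genes.assign(pvalue=[0.002] + [0.5] * 9)
        out2 = locus_eqtl_adjust(genes2).set_index("gene")
        assert out2.at["g0", "p_adjusted"] == pytest.approx(0.02)
        assert not out2.at["g0", "significant"]

    def test_empty_locus(self):
        out = locus_eqtl_adjust(pd.DataFrame({"gene": [], "pvalue": []}))
        assert len(out) == 0
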