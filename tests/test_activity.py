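"""Normalization and NB activity test: independent oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from mprakit import (bh_adjust, default_sample_sheet, fit_nb, size_factors,
                     simulate_barcode_map, simulate_counts, simulate_library,
                     simulate_truth)
from mprakit import test_activity as call_activity


def nb_loglik_scalar(y, mu, alpha):
    r = 1.0 / alpha
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(np.sum(special.gammaln(y + r) - special.gammaln(r)
                        - special.gammaln(y + 1) + r * np.log(r / (r + mu))
                        + y * np.log(mu / (r + mu))))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        c = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(size_factors(c), 1.0)

    def test_doubled_sample_scaling_exactness(self):
        base = np.array([10, 25, 40, 7, 100])
        c = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        sf = size_factors(c)
        # median-of-ratios exactness: c's factor exactly 2x a's
        assert np.isclose(sf["c"] / sf["a"], 2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        c = pd.DataFrame(rng.integers(1, 500, size=(50, 6)),
                         columns=[f"s{i}" for i in range(6)])
        sf = size_factors(c)
        # oracle: literal median-of-ratios definition, row by row
        mat = c.to_numpy(dtype=float)
        geomean = np.exp(np.mean(np.log(mat), axis=1))
        for j, col in enumerate(c.columns):
            ratios = mat[:, j] / geomean
            assert abs(sf[col] - np.median(ratios)) < 1e-12

    def test_zero_rows_excluded_from_reference(self):
        c = pd.DataFrame({"a": [10, 0, 30], "b": [10, 5, 30]})
        sf = size_factors(c)  # row with a zero is excluded
        assert np.allclose(sf, 1.0)

    def test_no_reference_oligo_is_error(self):
        c = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="median-of-ratios"):
            size_factors(c)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_textbook_definition_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_adjust(p)
            # oracle: q_i = min_{j: p_j >= p_i} (m * p_j / rank_j)
            m = len(p)
            order = np.argsort(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            expect = np.minimum.accumulate(ranked[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(expect, 1.0)
            assert np.allclose(q, out)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFitNB:
    def test_null_fit_is_zero(self):
        res = fit_nb([100, 110, 90], [100, 110, 90])
        assert abs(res["beta"]) < 1e-6

    def test_matches_2d_grid_search_mle(self):
        """Joint (β, α) MLE vs an exhaustive 2-D grid-search oracle on the
        canonical fixture and on 20 random small fixtures."""
        rng = np.random.default_rng(3)
        fixtures = [(np.array([100.0]), np.array([400.0, 380, 420, 410, 390]))]
        for _ in range(20):
            mu_d = rng.uniform(20, 300)
            fc = 2 ** rng.uniform(-2, 2)
            a = rng.uniform(0.01, 0.4)
            y_d = rng.negative_binomial(1 / a, 1 / (1 + a * mu_d), size=2).astype(float)
            y_r = rng.negative_binomial(1 / a, 1 / (1 + a * mu_d * fc), size=5).astype(float)
            if y_d.sum() == 0 or y_r.sum() == 0:
                continue
            fixtures.append((y_d, y_r))
        def grid_loglik(y, mu, la):
            # (n_mu, n_alpha) log-likelihood surface for one sample group
            r = 1.0 / np.exp(la)[None, :, None]
            muv = mu[:, None, None]
            yv = np.asarray(y, dtype=float)[None, None, :]
            return (special.gammaln(yv + r) - special.gammaln(r)
                    - special.gammaln(yv + 1) + r * np.log(r / (r + muv))
                    + yv * np.log(muv / (r + muv))).sum(axis=2)

        for y_d, y_r in fixtures:
            res = fit_nb(y_d, y_r)
            # oracle: dense grid over (log mu_r, log alpha); mu_d profiled
            # exactly (equal size factors -> group MLE mean = sample mean)
            m_d = y_d.mean()
            lm = np.linspace(np.log(max(y_r.mean(), 0.5)) - 0.4,
                             np.log(max(y_r.mean(), 0.5)) + 0.4, 641)
            la = np.linspace(np.log(1e-4), np.log(8), 361)
            ll = (grid_loglik(y_r, np.exp(lm), la)
                  + grid_loglik(y_d, np.array([m_d]), la))
            i, _ = np.unravel_index(np.argmax(ll), ll.shape)
            beta_oracle = (lm[i] - np.log(m_d)) / np.log(2)
            assert abs(res["beta"] - beta_oracle) < 1e-3

    def test_small_alpha_limit_matches_poisson_glm(self):
        """As α→0 the NB fit reproduces the Poisson GLM estimate (which has
        the closed form log2 of the group-mean ratio)."""
        y_d, y_r = [95, 105, 100], [210, 190, 200, 205]
        res = fit_nb(y_d, y_r, alpha=1e-10)
        poisson_beta = np.log2(np.mean(y_r) / np.mean(y_d))
        assert abs(res["beta"] - poisson_beta) < 1e-4

    def test_all_zero_counts_untestable(self):
        with pytest.raises(ValueError):
            fit_nb([0, 0], [0, 0, 0])


def _null_experiment(seed, n_elements=150, depth=None, alpha=(0.05, 0.5)):
    lib = simulate_library(n_elements, category_props=(0, 0.5, 0.5),
                           n_signals=1, frac_two_snp=0.0, seed=seed)
    truth = simulate_truth(lib, frac_active=0.0, frac_higher=0, frac_lower=0,
                           alpha_range=alpha, seed=seed)
    bm = simulate_barcode_map(lib, barcodes_per_oligo=1, seed=seed)
    samples = default_sample_sheet(n_rna=5, n_dna=1, conditions=("standard",))
    depth = depth or 200 * len(lib)
    counts = simulate_counts(lib, bm, truth, samples, depth=depth, seed=seed)
    counts.index = lib["oligo_id"]
    return lib, truth, samples, counts


class TestActivityCalls:
    def test_null_simulation_rarely_calls_active(self):
        flagged, total = 0, 0
        for seed in range(3):
            _, _, samples, counts = _null_experiment(seed)
            res = call_activity(counts, samples, "standard")
            flagged += int(res["active"].sum())
            total += int(res["tested"].sum())
        assert flagged / total <= 0.015

    def test_power_at_reference_effect_size(self):
        """β=1.5 log2 at base mean ≈200 with 5 replicates is called active
        for the large majority of truly active oligos."""
        lib = simulate_library(150, category_props=(0, 0.5, 0.5), n_signals=1,
                               frac_two_snp=0.0, seed=9)
        truth = simulate_truth(lib, frac_active=0.5, activity_log2fc=1.5,
                               frac_skew=0.0, alpha_range=(0.05, 0.5), seed=9)
        bm = simulate_barcode_map(lib, barcodes_per_oligo=30, seed=9)
        samples = default_sample_sheet(n_rna=5, n_dna=5, conditions=("standard",))
        counts = simulate_counts(lib, bm, truth, samples, depth=200 * len(lib) * 30,
                                 seed=9)
        from mprakit import BarcodeAssignment, aggregate_counts
        asg = BarcodeAssignment.from_frame(bm)
        oligo_counts, _ = aggregate_counts(counts, asg, oligo_ids=list(lib["oligo_id"]))
        res = call_activity(oligo_counts, samples, "standard")
        truly = truth.oligos.set_index("oligo_id")["activity_log2fc"] > 0
        called = res.set_index("oligo_id")["active"]
        sens = (called & truly).sum() / truly.sum()
        assert sens >= 0.8

    def test_scaling_stability(self):
        """Multiplying one sample's counts by c scales its size factor by
        exactly c relative to the others (median-of-ratios exactness).  The
        NB estimates are then stable: the extra counts carry real Fisher
        information, so β̂ and p shift only within a small fraction of their
        standard errors (exact invariance is impossible for a count
        likelihood — deeper sequencing genuinely changes the information)."""
        _, _, samples, counts = _null_experiment(5, n_elements=60)
        res1 = call_activity(counts, samples, "standard")
        sf1 = size_factors(counts)
        scaled = counts.copy()
        col = scaled.columns[2]
        scaled[col] = scaled[col] * 3
        res2 = call_activity(scaled, samples, "standard")
        sf2 = size_factors(scaled)
        ratio1 = sf1[col] / sf1[counts.columns[0]]
        ratio2 = sf2[col] / sf2[counts.columns[0]]
        assert np.isclose(ratio2 / ratio1, 3.0, rtol=1e-9)
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=0.06, equal_nan=True)
        assert np.allclose(res1["pvalue"], res2["pvalue"], atol=0.06, equal_nan=True)

    def test_sign_consistency_and_flags(self):
        _, _, samples, counts = _null_experiment(6, n_elements=60)
        res = call_activity(counts, samples, "standard")
        tested = res[res["tested"]]
        assert (np.sign(tested["stat"]) == np.sign(tested["log2fc"])).all()
        assert (res.loc[res["active"], "tested"]).all()
        assert (res.loc[res["active"], "log2fc"] > 0).all()

    def test_zero_plasmid_oligo_flagged_untested(self):
        _, _, samples, counts = _null_experiment(7, n_elements=40)
        counts.iloc[0, :] = [0] + [5] * (counts.shape[1] - 1)  # DNA first col
        res = call_activity(counts, samples, "standard")
        assert not res.loc[0, "tested"]
        assert np.isnan(res.loc[0, "pvalue"])

    def test_too_few_replicates_is_error(self):
        _, _, samples, counts = _null_experiment(8, n_elements=20)
        bad = samples[samples["sample_id"].isin(["dna_b1_r1", "rna_standard_r1"])]
        with pytest.raises(ValueError):
            call_activity(counts, bad, "standard")
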