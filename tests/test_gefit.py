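"""Global-epistasis fits, BH correction, slope comparisons, invariant slopes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pivotdfe as pdfe


def bh_stepup_oracle(p, alpha):
    """Direct step-up enumeration of the BH procedure."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        adj[idx] = min(1.0, min(m * p[order[j]] / (j + 1)
                                for j in range(rank - 1, m)))
    return reject, adj


class TestBenjaminiHochberg:
    def test_all_zero_pvalues_all_rejected(self):
        reject, adj = pdfe.benjamini_hochberg([0.0, 0.0, 0.0], 0.05)
        assert reject.all() and (adj == 0).all()

    def test_four_pvalue_example(self):
        # thresholds k*alpha/m = .0125, .025, .0375, .05
        reject, adj = pdfe.benjamini_hochberg([0.01, 0.02, 0.04, 0.2], 0.05)
        assert list(reject) == [True, True, False, False]
        assert adj == pytest.approx([0.04, 0.04, 4 * 0.04 / 3, 0.2])

    def test_two_pvalues_both_rejected(self):
        reject, _ = pdfe.benjamini_hochberg([0.01, 0.04], 0.05)
        assert reject.all()

    def test_single_pvalue_at_boundary(self):
        reject, adj = pdfe.benjamini_hochberg([0.049], 0.05)
        assert reject[0] and adj[0] == pytest.approx(0.049)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            pdfe.benjamini_hochberg([0.5, 1.2], 0.05)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_stepup_oracle(self, pvals, alpha):
        reject, adj = pdfe.benjamini_hochberg(pvals, alpha)
        oracle_rej, oracle_adj = bh_stepup_oracle(pvals, alpha)
        assert (reject == oracle_rej).all()
        assert adj == pytest.approx(oracle_adj)


class TestFitMutationEnv:
    def test_exact_line(self):
        res = pdfe.fit_mutation_env([0, 1, 2], [1, 3, 5])
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)
        assert res["f_p"] == 0.0

    def test_three_point_closed_form(self):
        # OLS on (0,0),(1,1),(2,1): slope 1/2, intercept 1/6, R^2 3/4
        res = pdfe.fit_mutation_env([0, 1, 2], [0, 1, 1])
        assert res["slope"] == pytest.approx(0.5)
        assert res["intercept"] == pytest.approx(1 / 6)
        assert res["r2"] == pytest.approx(0.75)
        assert res["residuals"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_constant_effects_flat_line(self):
        res = pdfe.fit_mutation_env([0.1, 0.2, 0.3, 0.4], [0.05] * 4)
        assert res["slope"] == 0.0
        assert res["f_p"] == pytest.approx(1.0)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            pdfe.fit_mutation_env([0, 1], [0, 1])


class TestFitAll:
    def test_noise_free_fits_are_exact(self, noise_free_dataset):
        growth, effects, truth = noise_free_dataset
        res = pdfe.fit_all(effects, growth)
        merged = res.fits.merge(truth.slopes.rename("b_true").reset_index(),
                                on="mutation")
        assert np.allclose(merged["slope"], merged["b_true"], atol=1e-9)
        assert np.allclose(res.fits["r2"], 1.0, atol=1e-9)
        assert res.residuals["resid"].abs().max() < 1e-9

    def test_significant_slopes_mostly_negative(self, default_fits):
        s = default_fits.summary
        assert s["frac_negative_among_significant_slopes"] >= 0.90

    def test_residuals_sum_to_zero_per_fit(self, default_fits):
        sums = default_fits.residuals.groupby(
            ["mutation", "environment"])["resid"].sum()
        assert sums.abs().max() < 1e-10

    def test_pooled_model_f_test_bh_family_is_mutations(self, default_fits):
        tests = default_fits.mutation_tests
        assert len(tests) == 94
        assert {"f_p", "f_p_bh", "significant"} <= set(tests.columns)

    def test_slopes_and_intercepts_anticorrelated(self, default_fits):
        assert (default_fits.slope_intercept_corr["pearson_r"] < -0.9).all()


class TestCompareSlopes:
    def _fits(self, rows):
        return pd.DataFrame(rows, columns=["mutation", "environment", "slope",
                                           "se_slope", "n"])

    def test_identical_slopes(self):
        fits = self._fits([("m1", "e1", -0.5, 0.1, 40),
                           ("m1", "e2", -0.5, 0.1, 40)])
        pairs, _, _ = pdfe.compare_slopes_pairwise(fits)
        assert pairs["t"].iloc[0] == 0.0
        assert pairs["p"].iloc[0] == pytest.approx(1.0)

    def test_welch_t_statistic(self):
        fits = self._fits([("m1", "e1", -0.5, 0.1, 1000),
                           ("m1", "e2", 0.5, 0.1, 1000)])
        pairs, _, _ = pdfe.compare_slopes_pairwise(fits)
        assert abs(pairs["t"].iloc[0]) == pytest.approx(7.0711, abs=1e-3)
        assert pairs["p"].iloc[0] < 1e-3

    def test_invariant_truth_mostly_indistinguishable(self, default_fits):
        """True slopes are environment-independent, so after BH most
        pairwise comparisons should not reject."""
        _, _, summary = pdfe.compare_slopes_pairwise(default_fits.fits)
        assert summary["frac_pairs_indistinguishable"] >= 0.80


class TestInvariantSlope:
    def test_identical_slopes_no_noise(self):
        lam = np.tile(np.linspace(0.1, 0.5, 10), 2)
        env = np.repeat(["e1", "e2"], 10)
        y = -0.5 * lam + np.where(env == "e1", 0.2, 0.3)
        res = pdfe.fit_invariant_slope(lam, y, env)
        assert res["slope"] == pytest.approx(-0.5)
        assert res["r2_shared"] == pytest.approx(1.0)
        assert res["delta_r2"] == pytest.approx(0.0, abs=1e-12)

    def test_truly_different_slopes_full_model_wins(self):
        lam = np.tile(np.linspace(0.1, 0.5, 10), 2)
        env = np.repeat(["e1", "e2"], 10)
        y = np.where(env == "e1", -1.0, 1.0) * lam
        res = pdfe.fit_invariant_slope(lam, y, env)
        assert res["r2_full"] == pytest.approx(1.0)
        assert res["r2_shared"] < res["r2_full"]

    def test_nesting_inequality_on_default_data(self, default_dataset):
        growth, effects, _ = default_dataset
        per_mut, _, summary = pdfe.fit_invariant_all(effects, growth)
        assert (per_mut["r2_shared"] <= per_mut["r2_full"] + 1e-12).all()
        assert summary["mean_delta_r2"] < 0.05

    def test_recovers_true_slopes_within_2se(self, default_dataset):
        growth, effects, truth = default_dataset
        per_mut, _, _ = pdfe.fit_invariant_all(effects, growth)
        merged = per_mut.merge(truth.slopes.rename("b_true").reset_index(),
                               on="mutation")
        covered = (np.abs(merged["slope"] - merged["b_true"])
                   <= 2 * merged["se_slope"])
        assert covered.mean() >= 0.90
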