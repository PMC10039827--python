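"""Path-model fitting: OLS, Poisson IRLS, AICc, all-subsets selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from agrisem.regression import (
    DegenerateInputError,
    aicc,
    all_subsets_selection,
    design_matrix,
    fit_linear,
    fit_poisson,
    standardize,
)


class TestStandardize:
    def test_hand_example(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        z = standardize(rng.normal(5, 3, 100))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize([5, 5, 5])


class TestFitLinear:
    def test_perfect_fit_identity(self):
        x = standardize(np.arange(10.0))
        X = np.column_stack([np.ones(10), x])
        fit = fit_linear(x, X, ("x",))
        assert fit.coef("x") == pytest.approx(1.0)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_slope_recovered_exactly(self):
        x = np.linspace(-2, 2, 50)
        y = 2.0 * x
        fit = fit_linear(y, np.column_stack([np.ones(50), x]), ("x",))
        assert fit.coef("x") == pytest.approx(2.0, abs=1e-12)

    def test_estimates_within_three_se_of_truth(self):
        rng = np.random.default_rng(7)
        n = 5000
        x1, x2 = rng.standard_normal((2, n))
        y = 0.6 * x1 - 0.3 * x2 + rng.standard_normal(n)
        fit = fit_linear(y, np.column_stack([np.ones(n), x1, x2]), ("x1", "x2"))
        assert abs(fit.coef("x1") - 0.6) < 3 * fit.se("x1")
        assert abs(fit.coef("x2") + 0.3) < 3 * fit.se("x2")

    def test_rank_deficiency_names_terms(self):
        x = np.arange(20.0)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(DegenerateInputError, match="rank"):
            fit_linear(x, X, ("a", "b"))

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(21)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = X @ [1.0, 0.5, -0.2, 0.0] + rng.standard_normal(n)
        fit = fit_linear(y, X, ("a", "b", "c"))
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-8)
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-10)


class TestFitPoisson:
    def test_intercept_only_is_log_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        fit = fit_poisson(y, np.ones((3, 1)))
        assert fit.coefficients[0] == pytest.approx(math.log(2.0), abs=1e-9)

    def test_constant_counts_give_log_constant(self):
        y = np.full(30, 4.0)
        fit = fit_poisson(y, np.ones((30, 1)))
        assert fit.coefficients[0] == pytest.approx(math.log(4.0), abs=1e-9)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DegenerateInputError, match="all-zero"):
            fit_poisson(np.zeros(20), np.ones((20, 1)))

    def test_estimates_within_three_se_of_truth(self):
        rng = np.random.default_rng(13)
        n = 5000
        x = rng.standard_normal(n)
        y = rng.poisson(np.exp(1.0 + 0.4 * x))
        fit = fit_poisson(y, np.column_stack([np.ones(n), x]), ("x",))
        assert abs(fit.coefficients[0] - 1.0) < 3 * fit.standard_errors[0]
        assert abs(fit.coef("x") - 0.4) < 3 * fit.se("x")

    def test_matches_statsmodels_glm(self):
        rng = np.random.default_rng(5)
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.poisson(np.exp(X @ [1.2, 0.3, -0.4]))
        fit = fit_poisson(y, X, ("a", "b"))
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-7)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-9)

    def test_fitted_means_sum_to_observed_sum(self):
        rng = np.random.default_rng(3)
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.poisson(np.exp(1.0 + 0.5 * X[:, 1]))
        fit = fit_poisson(y, X, ("x",))
        mu = np.exp(X @ np.array(fit.coefficients))
        assert mu.sum() == pytest.approx(y.sum(), rel=1e-8)


class TestAicc:
    def test_hand_computation(self):
        assert aicc(-10.0, 2, 100) == pytest.approx(24 + 12 / 97)

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-10.0) + 2 * 3
        assert aicc(-10.0, 3, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_more_params_cost_more_at_equal_loglik(self):
        assert aicc(-10.0, 3, 50) > aicc(-10.0, 2, 50)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 10, 11)


class TestAllSubsets:
    @staticmethod
    def _table(n=500, seed=0, signal=0.8):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
                "x3": rng.standard_normal(n),
            }
        )
        df["y"] = signal * df["x1"] + rng.standard_normal(n)
        return df

    def test_two_predictors_give_four_candidates(self):
        df = self._table(n=80)
        res = all_subsets_selection("y", ["x1", "x2"], df, "gaussian")
        assert len(res.candidates) == 4
        term_sets = {fit.terms for fit, _, _ in res.candidates}
        assert term_sets == {(), ("x1",), ("x2",), ("x1", "x2")}

    def test_strong_signal_predictor_labelled_strong(self):
        df = self._table()
        res = all_subsets_selection("y", ["x1", "x2", "x3"], df, "gaussian")
        assert res.support["x1"] == "strong"
        assert "x1" in res.candidates[0][0].terms
        assert res.effect_coefficients["x1"] == pytest.approx(0.8, abs=0.15)

    def test_pure_noise_keeps_null_near_top(self):
        null_near_top = 0
        any_strong = 0
        for seed in range(100):
            df = self._table(n=200, seed=seed, signal=0.0)
            res = all_subsets_selection("y", ["x1", "x2"], df, "gaussian")
            null_delta = next(d for f, _, d in res.candidates if f.terms == ())
            null_near_top += null_delta <= 2.0
            any_strong += any(s == "strong" for s in res.support.values())
        assert null_near_top >= 80
        # a noise predictor reaches the top model only when its chi-square
        # improvement exceeds the AICc penalty (~15% per predictor)
        assert any_strong <= 45

    def test_ranking_invariant_to_predictor_order(self):
        df = self._table(n=150, seed=4)
        a = all_subsets_selection("y", ["x1", "x2", "x3"], df, "gaussian")
        b = all_subsets_selection("y", ["x3", "x1", "x2"], df, "gaussian")
        assert [f.terms for f, _, _ in a.candidates] == [f.terms for f, _, _ in b.candidates]
        assert a.support == b.support
        assert a.effect_coefficients == b.effect_coefficients

    def test_top_model_has_zero_delta_and_weak_definition_holds(self):
        df = self._table(n=150, seed=9, signal=0.3)
        res = all_subsets_selection("y", ["x1", "x2", "x3"], df, "gaussian")
        assert res.candidates[0][2] == 0.0
        top_terms = set(res.candidates[0][0].terms)
        for g, label in res.support.items():
            in_window = any(
                d <= 2.0 and g in f.terms for f, _, d in res.candidates
            )
            if label == "strong":
                assert g in top_terms
            elif label == "weak":
                assert g not in top_terms and in_window
            else:
                assert g not in top_terms and not in_window

    def test_quadratic_pair_moves_together(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "z": z, "y": 0.5 * x - 0.6 * x**2 + rng.standard_normal(n)})
        res = all_subsets_selection("y", ["x+x^2", "z"], df, "gaussian")
        for f, _, _ in res.candidates:
            assert ("x" in f.terms) == ("x^2" in f.terms)
        assert res.support["x+x^2"] == "strong"
        assert res.effect_coefficients["x^2"] == pytest.approx(-0.6, abs=0.2)


class TestCoverage:
    def test_confidence_interval_coverage_at_study_size(self):
        """95% CIs on path coefficients cover truth at the nominal rate
        (pooled over coefficients, 200 replicates at n=127)."""
        from scipy import stats

        truth = np.array([0.4, -0.3])
        n, reps = 127, 200
        covered = total = 0
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
            y = X @ np.concatenate([[0.0], truth]) + rng.standard_normal(n)
            fit = fit_linear(y, X, ("a", "b"))
            tcrit = stats.t.ppf(0.975, fit.df_resid)
            for term, beta in zip(("a", "b"), truth):
                half = tcrit * fit.se(term)
                covered += abs(fit.coef(term) - beta) <= half
                total += 1
        rate = covered / total
        assert 0.91 <= rate <= 0.99
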