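"""Bivariate logistic regression: predictors, likelihood, fitting, prediction."""

import numpy as np
import pytest
from scipy import special

from bivbin.bivlogit import (
    BivariateLogisticRegression,
    BivLogitParams,
    DesignMap,
    linear_predictors,
    loglikelihood,
)
from bivbin.dataset import BivariateBinaryDataset
from bivbin.joint import joint_probs
from bivbin.simulate import effect_cohort_spec, generate_dataset, generate_outcomes


def intercept_only(b1, b2, b3):
    return BivLogitParams([b1], [b2], [b3], DesignMap((), (), ()))


class TestLinearPredictors:
    def test_zero_betas_give_half_half_one(self):
        params = BivLogitParams([0, 0], [0, 0], [0], DesignMap((0,), (0,), ()))
        pi1, pi2, psi = linear_predictors(params, np.array([[1.7], [-2.2]]))
        np.testing.assert_allclose(pi1, 0.5)
        np.testing.assert_allclose(pi2, 0.5)
        np.testing.assert_allclose(psi, 1.0)

    def test_intercept_log3_gives_three_quarters(self):
        params = intercept_only(np.log(3), 0.0, 0.0)
        pi1, _, _ = linear_predictors(params, np.empty((5, 0)))
        np.testing.assert_allclose(pi1, 0.75)

    def test_matches_scalar_oracle(self):
        """Vectorized predictors equal a per-row scalar evaluation."""
        params = BivLogitParams(
            [0.3, -1.1, 0.6], [-0.2, 0.9, -0.4], [0.5, 0.25],
            DesignMap((0, 1), (0, 1), (1,)),
        )
        X = np.array([[1.5, -0.7], [-2.0, 0.3]])
        pi1, pi2, psi = linear_predictors(params, X)
        for i, row in enumerate(X):
            e1 = 0.3 + -1.1 * row[0] + 0.6 * row[1]
            e2 = -0.2 + 0.9 * row[0] + -0.4 * row[1]
            e3 = 0.5 + 0.25 * row[1]
            assert pi1[i] == pytest.approx(1 / (1 + np.exp(-e1)))
            assert pi2[i] == pytest.approx(1 / (1 + np.exp(-e2)))
            assert psi[i] == pytest.approx(np.exp(e3))

    def test_dimension_mismatch_raises(self):
        params = BivLogitParams([0, 0], [0, 0], [0], DesignMap((0,), (0,), ()))
        with pytest.raises(ValueError):
            linear_predictors(params, np.empty((3, 0)))


class TestLoglikelihood:
    def test_uniform_cells_single_row(self):
        params = intercept_only(0.0, 0.0, 0.0)
        for y1, y2 in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            d = BivariateBinaryDataset(np.empty((1, 0)), [y1], [y2])
            assert loglikelihood(params, d) == pytest.approx(np.log(0.25))

    def test_uniform_cells_all_four(self):
        params = intercept_only(0.0, 0.0, 0.0)
        d = BivariateBinaryDataset(np.empty((4, 0)), [0, 0, 1, 1], [0, 1, 0, 1])
        assert loglikelihood(params, d) == pytest.approx(4 * np.log(0.25))

    def test_matches_brute_force_oracle(self):
        """Row-by-row recomputation of each realized cell probability."""
        rng = np.random.default_rng(20)
        X = rng.normal(size=(20, 2))
        d = BivariateBinaryDataset(X, rng.integers(0, 2, 20), rng.integers(0, 2, 20))
        params = BivLogitParams(
            [0.2, 0.7, -0.5], [-0.3, 0.1, 0.4], [0.6],
            DesignMap((0, 1), (0, 1), ()),
        )
        expected = 0.0
        for i in range(20):
            e1 = params.beta1 @ np.r_[1, X[i]]
            e2 = params.beta2 @ np.r_[1, X[i]]
            t = joint_probs(special.expit(e1), special.expit(e2), np.exp(0.6))
            cell = {
                (1, 1): t.pi11, (1, 0): t.pi10, (0, 1): t.pi01, (0, 0): t.pi00,
            }[(int(d.y1[i]), int(d.y2[i]))]
            expected += np.log(cell)
        assert loglikelihood(params, d) == pytest.approx(expected, rel=1e-12)


class TestFit:
    def test_intercept_only_psi_equals_sample_odds_ratio(self, reconstructed_outcomes):
        """The saturated intercept-only MLE reproduces the empirical 2x2 table."""
        y1, y2 = reconstructed_outcomes
        est = BivariateLogisticRegression().fit(
            np.empty((len(y1), 0)), np.column_stack([y1, y2])
        )
        psi_hat = np.exp(est.params_.beta3[0])
        assert psi_hat == pytest.approx((14 * 34) / (207 * 8), abs=1e-4)
        assert est.converged_
        assert np.all(est.se_ > 0)

    def test_psi_fixed_reduces_to_univariate_logits(self):
        """With no dependence parameters the fit must equal two independent
        logistic regressions (statsmodels is the oracle)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(400, 2))
        true = BivLogitParams([0.2, 0.5, -0.3], [-0.4, 0.6, 0.2], [],
                              DesignMap((0, 1), (0, 1), None))
        y1, y2 = generate_outcomes(true, X, seed=9)
        est = BivariateLogisticRegression(dependence="none").fit(
            X, np.column_stack([y1, y2])
        )
        m1 = sm.Logit(y1, sm.add_constant(X)).fit(disp=0)
        m2 = sm.Logit(y2, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(est.params_.beta1, m1.params, atol=1e-4)
        np.testing.assert_allclose(est.params_.beta2, m2.params, atol=1e-4)

    def test_mle_dominates_truth_on_own_sample(self):
        spec = effect_cohort_spec(seed=5, n=300)
        data = generate_dataset(spec)
        est = BivariateLogisticRegression().fit(data)
        # the fitted design has intercept-only psi, same as the generator
        ll_true = loglikelihood(spec.true_params, data)
        assert est.loglik_ >= ll_true - 1e-6

    def test_single_class_outcome_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 1))
        with pytest.raises(ValueError, match="single class"):
            BivariateLogisticRegression().fit(X, np.column_stack(
                [np.ones(50), np.r_[np.ones(25), np.zeros(25)]]))

    def test_se_shrinks_like_root_n(self):
        """Doubling n should shrink the median SE by roughly 1/sqrt(2)."""
        ratios = []
        for rep in range(20):
            se = {}
            for n in (500, 1000):
                spec = effect_cohort_spec(seed=10_000 + 13 * rep + n, n=n)
                data = generate_dataset(spec)
                est = BivariateLogisticRegression().fit(data)
                se[n] = est.se_
            ratios.append(np.median(se[1000] / se[500]))
        med = np.median(ratios)
        assert 0.65 <= med <= 0.78


class TestPredict:
    def test_marginal_threshold_tie_goes_to_zero(self):
        params = intercept_only(0.0, 0.0, 0.0)
        est = BivariateLogisticRegression()
        est.params_ = params
        pred = est.predict(np.empty((3, 0)), rule="marginal-threshold")
        assert np.all(pred == 0)

    @pytest.mark.parametrize(
        "cells, expected",
        [
            # (pi00, pi01, pi10, pi11): exact four-way tie -> (0,0) wins
            ((0.25, 0.25, 0.25, 0.25), (0, 0)),
            # tie between (0,0) and (1,1) -> priority goes to (0,0)
            ((0.4, 0.1, 0.1, 0.4), (0, 0)),
            ((0.1, 0.2, 0.2, 0.5), (1, 1)),
        ],
    )
    def test_joint_argmax_tiebreaks(self, cells, expected, monkeypatch):
        est = BivariateLogisticRegression()
        est.params_ = intercept_only(0.0, 0.0, 0.0)
        monkeypatch.setattr(
            est, "predict_joint_proba", lambda X: np.tile(cells, (len(X), 1))
        )
        pred = est.predict(np.empty((2, 0)), rule="joint-argmax")
        assert tuple(pred[0]) == expected

    def test_unknown_rule_rejected(self):
        est = BivariateLogisticRegression()
        est.params_ = intercept_only(0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="unknown prediction rule"):
            est.predict(np.empty((1, 0)), rule="bayes")
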