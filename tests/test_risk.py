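"""Unit tests for the multiplicative risk model and its cloglog GLM."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from wvcrisk.risk import (
    RiskCoefficients,
    cloglog,
    cloglog_inv,
    collision_rate,
    fit_alternative_glm,
    fit_collision_glm,
    roc_auc,
    sequential_deviance_anova,
)
from wvcrisk.synthetic import simulate_collisions


def simulate_loguniform(n, seed, betas=(-4.0, 1.0, 1.0, 1.0)):
    """Segments with log-uniform O, V, S and outcomes from the rate model."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "segment_id": np.arange(n).astype(str),
            "O": np.exp(rng.uniform(math.log(0.05), 0.0, n)),
            "V": np.exp(rng.uniform(math.log(5.0), math.log(500.0), n)),
            "S": np.exp(rng.uniform(math.log(2.0), math.log(20.0), n)),
        }
    )
    return simulate_collisions(table, RiskCoefficients(*betas), seed)


def direct_mle(records: pd.DataFrame) -> np.ndarray:
    """Independent oracle: direct maximization of the exact log-likelihood.

    Uses ln(1-p) = -exp(eta), so the Bernoulli log-likelihood is
    y*ln(-expm1(-exp(eta))) - (1-y)*exp(eta); maximized by quasi-Newton
    descent, not IRLS.
    """
    X = np.column_stack(
        [
            np.ones(len(records)),
            np.log(records["O"]),
            np.log(records["V"]),
            np.log(records["S"]),
        ]
    )
    y = records["Y"].to_numpy(dtype=float)

    def nll(beta):
        eta = np.clip(X @ beta, -30, 3.5)
        mu = -np.expm1(-np.exp(eta))
        return -np.sum(y * np.log(np.clip(mu, 1e-300, None)) - (1 - y) * np.exp(eta))

    res = minimize(nll, np.zeros(4), method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    return res.x


class TestLink:
    def test_unit_rate_maps_to_zero(self):
        assert abs(cloglog(1 - math.exp(-1))) < 1e-12

    def test_half_matches_high_precision_value(self):
        # ln(ln 2), frozen from 20-digit symbolic evaluation
        assert cloglog(0.5) == pytest.approx(-0.36651292058166433, abs=1e-14)

    def test_inverse_at_zero(self):
        assert cloglog_inv(0.0) == pytest.approx(0.6321205588285577, abs=1e-14)

    def test_inverse_limits(self):
        assert cloglog_inv(-60.0) == pytest.approx(0.0, abs=1e-20)
        assert cloglog_inv(60.0) == 1.0

    def test_inverse_of_ln_ln2_is_half(self):
        assert cloglog_inv(math.log(math.log(2.0))) == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            cloglog(bad)

    def test_roundtrip_over_probability_range(self):
        p = np.concatenate(
            [np.geomspace(1e-9, 0.5, 200), 1 - np.geomspace(1e-9, 0.5, 200)]
        )
        err = np.abs(cloglog_inv(cloglog(p)) - p)
        assert err.max() < 1e-10

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=-15.0, max_value=3.0))
    def test_links_are_mutually_inverse_and_monotone(self, eta):
        p = cloglog_inv(eta)
        assert 0.0 < p < 1.0
        # eta-space precision degrades as p approaches 1 (1-p underflows
        # relative precision); the p-space roundtrip is tested separately
        assert cloglog(p) == pytest.approx(eta, abs=1e-7)
        assert cloglog_inv(eta + 0.1) > p


class TestCollisionRate:
    def test_identity_coefficients(self):
        assert collision_rate(1.0, 1.0, 1.0, RiskCoefficients(0, 1, 1, 1)) == pytest.approx(1.0)

    def test_exact_multiplicative_form(self):
        # a = 2: rate must equal a * O * V * S
        rate = collision_rate(0.5, 4.0, 2.0, RiskCoefficients(math.log(2), 1, 1, 1))
        assert rate == pytest.approx(8.0, rel=1e-12)

    def test_reported_scale_coefficients_match_high_precision_oracle(self):
        # frozen from 20-digit symbolic evaluation of
        # exp(-12.82 + 0.6583 ln 0.5 + 0.2715 ln 2000 + 2.694 ln 100)
        rate = collision_rate(0.5, 2000.0, 100.0, RiskCoefficients(-12.82, 0.6583, 0.2715, 2.694))
        assert rate == pytest.approx(3.2991824978381895, rel=1e-12)

    def test_unit_beta_rate_equals_a_OVS_vectorised(self):
        rng = np.random.default_rng(0)
        O = rng.uniform(0.01, 1, 100)
        V = rng.uniform(1, 1e4, 100)
        S = rng.uniform(10, 120, 100)
        coefs = RiskCoefficients(-9.3, 1, 1, 1)
        np.testing.assert_allclose(
            collision_rate(O, V, S, coefs), math.exp(-9.3) * O * V * S, rtol=1e-12
        )

    @pytest.mark.parametrize("O,V,S", [(0.0, 1, 1), (0.5, -2, 1), (0.5, 1, 0.0), (1.5, 1, 1)])
    def test_domain_errors(self, O, V, S):
        with pytest.raises(ValueError):
            collision_rate(O, V, S, RiskCoefficients(0, 1, 1, 1))


class TestCollisionGLM:
    def test_exact_proportionality_recovery(self):
        """Simulated under unit coefficients, the GLM recovers them."""
        data = simulate_loguniform(50_000, seed=1)
        fit = fit_collision_glm(data)
        coefs = fit.coefficients["coef"]
        assert abs(coefs["ln_O"] - 1.0) < 0.05
        assert abs(coefs["ln_V"] - 1.0) < 0.05
        assert abs(coefs["ln_S"] - 1.0) < 0.05
        assert abs(coefs["const"] - (-4.0)) < 0.1

    def test_matches_direct_likelihood_oracle(self):
        data = simulate_loguniform(200, seed=7)
        fit = fit_collision_glm(data)
        oracle = direct_mle(data)
        np.testing.assert_allclose(
            fit.coefficients["coef"].to_numpy(), oracle, atol=1e-3
        )

    def test_null_data_shows_no_signal(self):
        """Outcome independent of predictors: tiny deviance, small z."""
        rng = np.random.default_rng(5)
        data = simulate_loguniform(10_000, seed=5)
        data["Y"] = rng.permutation(data["Y"].to_numpy())
        fit = fit_collision_glm(data)
        assert fit.deviance_explained < 1.0
        assert np.abs(fit.coefficients["z"][1:]).max() < 3.5

    def test_single_class_outcome_rejected(self):
        data = simulate_loguniform(100, seed=2)
        data["Y"] = 0
        with pytest.raises(ValueError, match="both"):
            fit_collision_glm(data)

    def test_nonpositive_predictor_rejected(self):
        data = simulate_loguniform(100, seed=2)
        data.loc[0, "V"] = -1.0
        with pytest.raises(ValueError):
            fit_collision_glm(data)

    def test_link_consistency_of_fitted_probabilities(self):
        data = simulate_loguniform(2000, seed=3)
        fit = fit_collision_glm(data)
        X = np.column_stack(
            [np.ones(len(data)), np.log(data["O"]), np.log(data["V"]), np.log(data["S"])]
        )
        eta = X @ fit.coefficients["coef"].to_numpy()
        fitted = np.asarray(fit.result.fittedvalues)
        from wvcrisk.risk import cloglog_inv as inv

        np.testing.assert_allclose(fitted, inv(eta), atol=1e-10)

    def test_aic_equals_minus_two_loglik_plus_two_k(self):
        data = simulate_loguniform(2000, seed=4)
        fit = fit_collision_glm(data)
        p = np.asarray(fit.result.fittedvalues)
        y = data["Y"].to_numpy()
        loglik = np.sum(np.log(np.where(y == 1, p, 1 - p)))
        assert fit.aic == pytest.approx(-2 * loglik + 2 * 4, rel=1e-9)


class TestAlternativeGLM:
    def _records(self, n=3000, seed=9):
        data = simulate_loguniform(n, seed=seed)
        rng = np.random.default_rng(seed)
        # raw covariates correlated with the structured predictors
        data["C1"] = np.log(data["O"]) + rng.normal(0, 0.3, n)
        data["C2"] = np.log(data["V"]) + rng.normal(0, 0.3, n)
        data["C3"] = np.log(data["S"]) + rng.normal(0, 0.3, n)
        return data

    def test_close_to_structured_model_on_structured_data(self):
        data = self._records()
        structured = fit_collision_glm(data)
        flat = fit_alternative_glm(data, covariates=["C1", "C2", "C3"])
        assert abs(flat.deviance_explained - structured.deviance_explained) < 5.0

    def test_duplicated_column_is_rejected(self):
        data = self._records(500)
        data["C1_copy"] = data["C1"]
        with pytest.raises(ValueError, match="rank"):
            fit_alternative_glm(data, covariates=["C1", "C1_copy", "C2"])

    def test_predictor_order_invariance(self):
        data = self._records(1000)
        a = fit_alternative_glm(data, covariates=["C1", "C2", "C3"])
        b = fit_alternative_glm(data, covariates=["C3", "C1", "C2"])
        assert a.deviance_explained == pytest.approx(b.deviance_explained, abs=1e-8)
        assert a.aic == pytest.approx(b.aic, abs=1e-6)


class TestSequentialAnova:
    def _design(self, n=1500, seed=11):
        data = simulate_loguniform(n, seed=seed)
        X = pd.DataFrame(
            {"ln_O": np.log(data["O"]), "ln_V": np.log(data["V"]), "ln_S": np.log(data["S"])}
        )
        return data["Y"].to_numpy(), X

    def test_single_term_share_is_one(self):
        y, X = self._design()
        shares = sequential_deviance_anova(y, X[["ln_V"]], ["ln_V"])
        assert shares["ln_V"] == pytest.approx(1.0, abs=1e-10)

    def test_shares_sum_to_one_for_every_order(self):
        import itertools

        y, X = self._design()
        for order in itertools.permutations(["ln_O", "ln_V", "ln_S"]):
            shares = sequential_deviance_anova(y, X, list(order))
            assert shares.sum() == pytest.approx(1.0, abs=1e-10)
            assert (shares >= -1e-12).all()

    def test_matches_nested_refit_oracle(self):
        """Shares equal deviance drops of independently refit nested models."""
        y, X = self._design(800, seed=12)
        order = ["ln_S", "ln_O", "ln_V"]
        shares = sequential_deviance_anova(y, X, order)

        def nested_deviance(cols):
            M = np.column_stack([np.ones(len(y))] + [X[c].to_numpy() for c in cols])

            def nll(beta):
                eta = np.clip(M @ beta, -30, 3.5)
                mu = np.clip(-np.expm1(-np.exp(eta)), 1e-12, 1 - 1e-12)
                return -np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))

            res = minimize(nll, np.zeros(M.shape[1]), method="BFGS",
                           options={"gtol": 1e-10, "maxiter": 500})
            return 2 * res.fun

        devs = [nested_deviance(order[: k + 1]) for k in range(-1, len(order))]
        drops = -np.diff(devs)
        np.testing.assert_allclose(shares.to_numpy(), drops / drops.sum(), atol=1e-6)

    def test_bad_order_rejected(self):
        y, X = self._design(300)
        with pytest.raises(ValueError, match="permutation"):
            sequential_deviance_anova(y, X, ["ln_O", "ln_V"])


class TestRocAuc:
    def test_perfect_and_reversed_ranking(self):
        labels = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 5000)
        scores = rng.uniform(size=5000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.05

    def test_ties_match_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 5, 60).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 60)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert roc_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
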