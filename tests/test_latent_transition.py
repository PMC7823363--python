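"""Latent transition model: likelihood, EM, transition summaries, odds ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietlta._arrays import CovariateScaler
from dietlta.latent_transition import (LTAParams, aggregate_transition_matrix,
                                       lta_em_fit, lta_loglik,
                                       membership_odds_ratios,
                                       transition_matrix,
                                       transition_matrix_grid)
from dietlta.synthetic import GeneratorConfig, generate_population

from conftest import (brute_force_lta_loglik, make_covariates, make_ordinal,
                      random_params, separated_rho)

SCALER = CovariateScaler(50.0, 19.0)


def tiny_lta_instance(rng, N=3, J=2, K=2):
    rho, beta1, a, gamma = random_params(rng, J, K)
    Y = rng.integers(0, 3, size=(N, 2, J))
    ages = rng.uniform(18, 84, N)
    sexes = rng.integers(0, 2, N)
    X = SCALER.design(ages, sexes)
    params = LTAParams(rho=rho, beta1=beta1, trans_intercepts=a, gamma=gamma,
                       items=[f"it{j:02d}" for j in range(J)], scaler=SCALER,
                       constrained=False)
    return params, Y, X, make_ordinal(Y, days=(1, 2)), make_covariates(ages, sexes)


class TestLogLik:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        params, Y, X, ordinal, cov = tiny_lta_instance(rng)
        expected = brute_force_lta_loglik(params.rho, params.beta1,
                                          params.trans_intercepts, params.gamma,
                                          Y[:, 0, :], Y[:, 1, :], X)
        assert lta_loglik(params, ordinal, cov) == pytest.approx(expected, abs=1e-10)

    def test_single_class_collapses_to_two_day_product(self):
        rng = np.random.default_rng(1)
        params, Y, X, ordinal, cov = tiny_lta_instance(rng, N=4, J=3, K=1)
        expected = sum(np.log(params.rho[j, 0, Y[i, d, j]])
                       for i in range(4) for d in range(2) for j in range(3))
        assert lta_loglik(params, ordinal, cov) == pytest.approx(expected, abs=1e-10)

    def test_identity_transition_equals_shared_class_two_day_mixture(self):
        # with an (effectively) identity transition matrix both days share one
        # class, so the likelihood reduces to a mixture over a single class
        # index with doubled emissions
        rng = np.random.default_rng(2)
        params, Y, X, ordinal, cov = tiny_lta_instance(rng, N=5, J=2, K=2)
        params.trans_intercepts[:] = 0.0
        params.trans_intercepts[0, 0] = 60.0   # from 1 stay in 1
        params.trans_intercepts[1, 0] = -60.0  # from 2 stay in 2 (reference)
        params.gamma[:] = 0.0
        ll = lta_loglik(params, ordinal, cov)
        # oracle: shared-class mixture over stacked two-day responses
        from scipy.special import logsumexp
        total = 0.0
        for i in range(5):
            eta = np.append(X[i] @ params.beta1.T, 0.0)
            logpi = eta - logsumexp(eta)
            logem = np.array([
                sum(np.log(params.rho[j, k, Y[i, d, j]])
                    for d in range(2) for j in range(2))
                for k in range(2)])
            total += logsumexp(logpi + logem)
        assert ll == pytest.approx(total, abs=1e-8)


class TestEMFit:
    def test_loglik_non_decreasing_along_em_trace(self):
        rng = np.random.default_rng(3)
        for rep in range(10):
            Y = rng.integers(0, 3, size=(25, 2, 3))
            fit = lta_em_fit(make_ordinal(Y, days=(1, 2)),
                             make_covariates(rng.uniform(18, 84, 25),
                                             rng.integers(0, 2, 25)),
                             K=2, n_starts=1, seed=rep, max_iter=60)
            trace = np.asarray(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8 * (np.abs(trace[:-1]) + 1))

    def test_day2_copy_of_day1_concentrates_on_diagonal(self):
        config = GeneratorConfig(n_subjects=600, rho=separated_rho(6, 2),
                                 beta1=np.array([[0.2, 0.4, 0.3]]),
                                 trans_intercepts=np.array([[4.0], [-4.0]]),
                                 gamma=np.array([[0.0, 0.0]]))
        cohort = generate_population(config, seed=5)
        day1 = cohort.ordinal[cohort.ordinal["day"] == 1].copy()
        day2 = day1.copy()
        day2["day"] = 2
        ordinal = pd.concat([day1, day2], ignore_index=True)
        fit = lta_em_fit(ordinal, cohort.covariates, K=2, n_starts=3, seed=1)
        P = aggregate_transition_matrix(fit, cohort.covariates)
        assert np.diag(P).min() > 0.95

    def test_measurement_invariance_single_rho_object(self):
        rng = np.random.default_rng(6)
        Y = rng.integers(0, 3, size=(30, 2, 3))
        fit = lta_em_fit(make_ordinal(Y, days=(1, 2)),
                         make_covariates(rng.uniform(18, 84, 30),
                                         rng.integers(0, 2, 30)),
                         K=2, n_starts=1, seed=0, max_iter=50)
        # one shared rho parameterizes both days: there is no second array
        assert fit.params.rho.shape == (3, 2, 3)
        assert not hasattr(fit.params, "rho_day2")

    def test_joint_posterior_margins_match_day_posteriors(self):
        rng = np.random.default_rng(7)
        Y = rng.integers(0, 3, size=(30, 2, 3))
        fit = lta_em_fit(make_ordinal(Y, days=(1, 2)),
                         make_covariates(rng.uniform(18, 84, 30),
                                         rng.integers(0, 2, 30)),
                         K=2, n_starts=1, seed=0, max_iter=50)
        q = fit.joint_posterior
        assert np.allclose(q.sum(axis=(1, 2)), 1.0, atol=1e-8)
        assert np.allclose(q.sum(axis=2), fit.posterior, atol=1e-12)
        assert np.allclose(q.sum(axis=1), fit.posterior_day2, atol=1e-12)

    def test_constrained_loglik_never_exceeds_unconstrained(self):
        rng = np.random.default_rng(8)
        Y = rng.integers(0, 3, size=(80, 2, 4))
        ordinal = make_ordinal(Y, days=(1, 2))
        cov = make_covariates(rng.uniform(18, 84, 80), rng.integers(0, 2, 80))
        con = lta_em_fit(ordinal, cov, K=2, n_starts=4, seed=2,
                         constrain_covariate_effects=True)
        unc = lta_em_fit(ordinal, cov, K=2, n_starts=4, seed=2,
                         constrain_covariate_effects=False)
        assert con.loglik <= unc.loglik + 1e-6

    def test_constrained_fit_ties_gamma_to_membership_slopes(self):
        rng = np.random.default_rng(9)
        Y = rng.integers(0, 3, size=(40, 2, 3))
        fit = lta_em_fit(make_ordinal(Y, days=(1, 2)),
                         make_covariates(rng.uniform(18, 84, 40),
                                         rng.integers(0, 2, 40)),
                         K=2, n_starts=1, seed=0, max_iter=50)
        assert np.allclose(fit.params.gamma, fit.params.beta1[:, 1:], atol=1e-12)


class TestTransitionMatrix:
    def make_params(self, a, gamma, K=2):
        J = 2
        rho = np.full((J, K, 3), 1 / 3)
        beta1 = np.zeros((K - 1, 3))
        return LTAParams(rho=rho, beta1=beta1, trans_intercepts=a, gamma=gamma,
                         items=["a", "b"], scaler=SCALER, constrained=False)

    def test_all_zero_parameters_give_uniform_rows(self):
        params = self.make_params(np.zeros((3, 2)), np.zeros((2, 2)), K=3)
        P = transition_matrix(params, age=40, sex=1)
        assert np.allclose(P, 1 / 3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rows_sum_to_one_for_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        _, _, a, gamma = random_params(rng, 2, 3)
        params = self.make_params(a, gamma, K=3)
        P = transition_matrix(params, age=rng.uniform(18, 84),
                              sex=rng.integers(0, 2))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_positive_age_slope_gives_monotone_transition_probability(self):
        gamma = np.array([[0.8, 0.0]])  # destination 1 favored with age
        params = self.make_params(np.array([[0.1], [0.3]]), gamma, K=2)
        grid = transition_matrix_grid(params, np.linspace(18, 84, 30),
                                      np.zeros(30))
        for k in range(2):
            assert np.all(np.diff(grid[:, k, 0]) > 0)


class TestAggregateTransition:
    def test_identical_covariates_reduce_to_pointwise_matrix(self):
        config = GeneratorConfig(n_subjects=120, rho=separated_rho(5, 2),
                                 beta1=np.array([[0.3, 0.5, 0.4]]),
                                 trans_intercepts=np.array([[2.0], [-1.5]]),
                                 gamma=np.array([[0.3, 0.2]]))
        cohort = generate_population(config, seed=3)
        cohort.covariates["age"] = 47.0
        cohort.covariates["sex"] = 1
        fit = lta_em_fit(cohort.ordinal, cohort.covariates, K=2, n_starts=3,
                         seed=4)
        P_agg = aggregate_transition_matrix(fit, cohort.covariates)
        P_point = transition_matrix(fit.params, age=47.0, sex=1)
        assert np.allclose(P_agg, P_point, atol=1e-10)
        assert np.allclose(P_agg.sum(axis=1), 1.0, atol=1e-10)

    def test_two_subgroup_posterior_weighted_average(self):
        # hand-computed weighted mean of two per-subgroup matrices
        rng = np.random.default_rng(10)
        params, Y, X, ordinal, cov = tiny_lta_instance(rng, N=4, J=2, K=2)
        cov.loc[:1, ["age", "sex"]] = [30.0, 0]
        cov.loc[2:, ["age", "sex"]] = [70.0, 1]
        from dietlta.latent_class import FitResult

        post = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.1, 0.9]])
        fit = FitResult(params=params, loglik=0.0, aic=0, bic=0,
                        relative_entropy=0, n_params=0, posterior=post,
                        modal=post.argmax(1), converged=True, n_iter=1,
                        seed=0, start_logliks=[], best_start=0, loglik_trace=[],
                        subjects=np.array([f"s{i:04d}" for i in range(4)]),
                        joint_posterior=None, posterior_day2=post)
        P_a = transition_matrix(params, 30.0, 0)
        P_b = transition_matrix(params, 70.0, 1)
        expected = np.empty((2, 2))
        for k in range(2):
            w = post[:, k]
            stack = np.array([P_a[k], P_a[k], P_b[k], P_b[k]])
            expected[k] = (w[:, None] * stack).sum(0) / w.sum()
        P_agg = aggregate_transition_matrix(fit, cov)
        assert np.allclose(P_agg, expected, atol=1e-12)


@pytest.fixture(scope="module")
def fitted():
    config = GeneratorConfig(n_subjects=500, rho=separated_rho(6, 2),
                             beta1=np.array([[0.4, -0.6, 0.9]]),
                             trans_intercepts=np.array([[2.2], [-2.0]]),
                             gamma=np.array([[-0.6, 0.9]]))
    cohort = generate_population(config, seed=21)
    fit = lta_em_fit(cohort.ordinal, cohort.covariates, K=2, n_starts=2, seed=6)
    table = membership_odds_ratios(fit, cohort.ordinal, cohort.covariates)
    return fit, table


class TestOddsRatios:

    def test_or_is_exp_of_coefficient(self, fitted):
        _, table = fitted
        assert np.allclose(table["or"], np.exp(table["coef"]))

    def test_negative_coefficient_gives_or_below_one(self, fitted):
        _, table = fitted
        neg = table[table["coef"] < 0]
        assert (neg["or"] < 1).all()

    def test_ci_brackets_the_point_estimate(self, fitted):
        _, table = fitted
        assert ((table["ci_low"] < table["or"]) & (table["or"] < table["ci_high"])).all()

    def test_recovers_generating_effect_signs(self, fitted):
        fit, table = fitted
        # truth: class of interest has a negative age and positive sex effect;
        # alignment may swap classes, flipping both signs together
        age = table.loc[table["covariate"] == "age_per_year", "coef"].iloc[0]
        sex = table.loc[table["covariate"] == "sex", "coef"].iloc[0]
        assert age * sex < 0
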