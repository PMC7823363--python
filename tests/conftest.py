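"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from dietlta._arrays import CovariateScaler
from dietlta.synthetic import GeneratorConfig


# ---------------------------------------------------------------------------
# Brute-force likelihood oracles (independent of the package's vectorized path)
# ---------------------------------------------------------------------------

def brute_force_lca_loglik(rho, beta, Y, X):
    """Enumerate classes per subject; plain-python sum-product."""
    N, J = Y.shape
    K = rho.shape[1]
    total = 0.0
    for i in range(N):
        eta = [float(X[i] @ beta[k]) for k in range(K - 1)] + [0.0]
        Z = sum(math.exp(e) for e in eta)
        s = 0.0
        for k in range(K):
            term = math.exp(eta[k]) / Z
            for j in range(J):
                term *= rho[j, k, Y[i, j]]
            s += term
        total += math.log(s)
    return total


def brute_force_lta_loglik(rho, beta1, a, gamma, Y1, Y2, X):
    """Enumerate all (k, l) latent paths per subject."""
    N, J = Y1.shape
    K = rho.shape[1]
    total = 0.0
    for i in range(N):
        eta1 = [float(X[i] @ beta1[k]) for k in range(K - 1)] + [0.0]
        Z1 = sum(math.exp(e) for e in eta1)
        x = X[i, 1:]
        s = 0.0
        for k, l in itertools.product(range(K), range(K)):
            pi_k = math.exp(eta1[k]) / Z1
            eta_t = [float(a[k, m] + gamma[m] @ x) for m in range(K - 1)] + [0.0]
            Zt = sum(math.exp(e) for e in eta_t)
            t_kl = math.exp(eta_t[l]) / Zt
            term = pi_k * t_kl
            for j in range(J):
                term *= rho[j, k, Y1[i, j]] * rho[j, l, Y2[i, j]]
            s += term
        total += math.log(s)
    return total


def align_to_truth(rho_est: np.ndarray, rho_true: np.ndarray) -> np.ndarray:
    """Permutation ``order`` with ``rho_est[:, order]`` best matching ``rho_true``.

    Best-match assignment (Hungarian) on mean absolute rho differences.
    """
    K = rho_true.shape[1]
    cost = np.zeros((K, K))
    for k in range(K):
        for a in range(K):
            cost[k, a] = np.abs(rho_true[:, k, :] - rho_est[:, a, :]).mean()
    _, order = linear_sum_assignment(cost)
    return order


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def make_ordinal(Y: np.ndarray, days=(1,), items=None) -> pd.DataFrame:
    """Long ordinal table from an integer array (N, n_days, J) or (N, J)."""
    if Y.ndim == 2:
        Y = Y[:, None, :]
    N, D, J = Y.shape
    if items is None:
        items = [f"it{j:02d}" for j in range(J)]
    rows = []
    for i in range(N):
        for d_idx, day in enumerate(days):
            for j in range(J):
                rows.append({"subject_id": f"s{i:04d}", "day": day,
                             "item": items[j], "category": int(Y[i, d_idx, j])})
    return pd.DataFrame(rows)


def make_covariates(ages, sexes) -> pd.DataFrame:
    return pd.DataFrame({"subject_id": [f"s{i:04d}" for i in range(len(ages))],
                         "age": ages, "sex": sexes})


def random_params(rng, J, K, p=2):
    """Random valid (rho, beta, a, gamma) for oracle comparisons."""
    rho = rng.dirichlet(np.ones(3), size=(J, K))
    beta = rng.normal(scale=0.7, size=(K - 1, 1 + p))
    a = rng.normal(scale=0.7, size=(K, K - 1))
    gamma = rng.normal(scale=0.5, size=(K - 1, p))
    return rho, beta, a, gamma


# ---------------------------------------------------------------------------
# Generator configurations used across tests
# ---------------------------------------------------------------------------

def separated_rho(J: int, K: int, peak: float = 0.8) -> np.ndarray:
    """Well-separated item-response probabilities (distinct modal categories)."""
    rho = np.full((J, K, 3), (1 - peak) / 2)
    for j in range(J):
        for k in range(K):
            rho[j, k, (j + k) % 3] = peak
    return rho


@pytest.fixture(scope="session")
def recovery_config() -> GeneratorConfig:
    """The K=3, J=10 cohort configuration used for parameter recovery."""
    return GeneratorConfig(
        n_subjects=3000,
        rho=separated_rho(10, 3),
        beta1=np.array([[0.3, 0.5, 0.6], [0.0, 0.8, 0.7]]),
        trans_intercepts=np.array([[2.5, 0.8], [1.0, 2.5], [-1.0, -0.7]]),
        gamma=np.array([[0.25, 0.30], [0.30, 0.35]]),
    )


@pytest.fixture(scope="session")
def default_scaler() -> CovariateScaler:
    return CovariateScaler(age_mean=51.0, age_sd=(84 - 18) / np.sqrt(12))
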