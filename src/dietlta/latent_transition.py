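"""Two-occasion latent transition model with concomitant covariates.

Day-1 class membership follows a multinomial logit on age and sex; the
day-2 class follows a first-order Markov transition whose destination
logit has prior-state-specific intercepts and covariate slopes. Item
responses are measurement-invariant: one rho array serves both days.

With two occasions the E-step enumerates all K^2 latent paths (k, l)
exhaustively — no forward-backward recursion is needed, and the joint
posterior q_i(k, l) is formed directly from

    q_i(k, l) ∝ P(C1=k|x_i) P(C2=l|C1=k, x_i)
               prod_j rho[j,k,y_ij1] rho[j,l,y_ij2].

The covariate-effect constraint ties the destination slopes (gamma) to
the covariate block of the day-1 membership logit, so age and sex act on
class membership the same way on both days; transition intercepts remain
free per prior state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._arrays import CovariateScaler, covariates_to_design, ordinal_to_arrays
from ._logit import log_softmax_ref
from .latent_class import (DEFAULT_PROB_FLOOR, FitResult, _log_emissions,
                           classify_modal)
from .model_selection import count_params, information_criteria, relative_entropy


@dataclass
class LTAParams:
    """Parameters of the transition model.

    rho : (J, K, C) shared item-response probabilities (both days).
    beta1 : (K-1, 1+p) day-1 membership logit on (1, z_age, sex).
    trans_intercepts : (K, K-1) destination-logit intercepts a[k, l] for
        prior state k; the last destination is the reference.
    gamma : (K-1, p) destination-logit covariate slopes, shared across
        prior states; under the constrained fit this equals beta1[:, 1:].
    """

    rho: np.ndarray
    beta1: np.ndarray
    trans_intercepts: np.ndarray
    gamma: np.ndarray
    items: list[str]
    scaler: CovariateScaler | None = None
    constrained: bool = True

    @property
    def K(self) -> int:
        return self.rho.shape[1]

    @property
    def J(self) -> int:
        return self.rho.shape[0]

    def log_transition(self, X: np.ndarray) -> np.ndarray:
        """(N, K, K) log transition probabilities at design rows X."""
        Xc = X[:, 1:]  # covariate part (z_age, sex)
        eta = self.trans_intercepts[None, :, :] + (Xc @ self.gamma.T)[:, None, :]
        return log_softmax_ref(eta)

    def to_dict(self) -> dict:
        return {
            "model": "lta",
            "rho": self.rho.tolist(),
            "beta1": self.beta1.tolist(),
            "trans_intercepts": self.trans_intercepts.tolist(),
            "gamma": self.gamma.tolist(),
            "items": list(self.items),
            "age_mean": None if self.scaler is None else self.scaler.age_mean,
            "age_sd": None if self.scaler is None else self.scaler.age_sd,
            "constrained": self.constrained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LTAParams":
        scaler = None
        if d.get("age_mean") is not None:
            scaler = CovariateScaler(d["age_mean"], d["age_sd"])
        return cls(rho=np.asarray(d["rho"], float),
                   beta1=np.asarray(d["beta1"], float),
                   trans_intercepts=np.asarray(d["trans_intercepts"], float),
                   gamma=np.asarray(d["gamma"], float),
                   items=list(d["items"]), scaler=scaler,
                   constrained=bool(d.get("constrained", True)))


def _design_for(params, covariates: pd.DataFrame, subjects) -> np.ndarray:
    if params.scaler is None:
        X, _ = covariates_to_design(covariates, subjects)
        return X
    cov = covariates.drop_duplicates("subject_id").set_index("subject_id").loc[subjects]
    return params.scaler.design(cov["age"].to_numpy(float), cov["sex"].to_numpy(float))


def _e_step(params: LTAParams, Y1, Y2, X, prob_floor):
    logpi = log_softmax_ref(X @ params.beta1.T)  # (N, K)
    logT = params.log_transition(X)  # (N, K, K)
    le1 = _log_emissions(params.rho, Y1, prob_floor)
    le2 = _log_emissions(params.rho, Y2, prob_floor)
    logq = logpi[:, :, None] + logT + le1[:, :, None] + le2[:, None, :]
    ll_i = logsumexp(logq, axis=(1, 2))
    q = np.exp(logq - ll_i[:, None, None])
    return q, float(ll_i.sum()), logpi, logT


def lta_loglik(params: LTAParams, ordinal: pd.DataFrame, covariates: pd.DataFrame,
               prob_floor: float = DEFAULT_PROB_FLOOR) -> float:
    """Observed-data log-likelihood of a two-day ordinal table."""
    Y, subjects, items = ordinal_to_arrays(ordinal, days=(1, 2))
    if list(items) != list(params.items):
        raise ValueError("items mismatch between params and data")
    X = _design_for(params, covariates, subjects)
    _, ll, _, _ = _e_step(params, Y[:, 0, :], Y[:, 1, :], X, prob_floor)
    return ll


# ---------------------------------------------------------------------------
# M-step for the structural (logit) parameters
# ---------------------------------------------------------------------------

def _pack_structural(beta1, a, gamma, constrained):
    parts = [beta1.ravel(), a.ravel()]
    if not constrained:
        parts.append(gamma.ravel())
    return np.concatenate(parts)


def _unpack_structural(vec, K, p, constrained):
    n_b = (K - 1) * (1 + p)
    beta1 = vec[:n_b].reshape(K - 1, 1 + p)
    n_a = K * (K - 1)
    a = vec[n_b:n_b + n_a].reshape(K, K - 1)
    if constrained:
        gamma = beta1[:, 1:]
    else:
        gamma = vec[n_b + n_a:].reshape(K - 1, p)
    return beta1, a, gamma


def _structural_obj_grad(vec, X, m1, q, K, constrained):
    """Expected complete-data log-likelihood of the logit blocks and its gradient."""
    p = X.shape[1] - 1
    beta1, a, gamma = _unpack_structural(vec, K, p, constrained)
    Xc = X[:, 1:]

    logpi = log_softmax_ref(X @ beta1.T)  # (N, K)
    eta = a[None, :, :] + (Xc @ gamma.T)[:, None, :]
    logT = log_softmax_ref(eta)  # (N, K, K)

    obj = float(np.sum(m1 * logpi)) + float(np.sum(q * logT))

    resid_pi = m1 - np.exp(logpi)  # rows of m1 sum to 1
    g_beta1 = resid_pi[:, : K - 1].T @ X  # (K-1, 1+p)
    resid_T = q - m1[:, :, None] * np.exp(logT)  # (N, K, K)
    g_a = resid_T[:, :, : K - 1].sum(axis=0)  # (K, K-1)
    g_gamma = np.einsum("ikl,ip->lp", resid_T[:, :, : K - 1], Xc)  # (K-1, p)

    if constrained:
        g_beta1 = g_beta1.copy()
        g_beta1[:, 1:] += g_gamma
        grad = np.concatenate([g_beta1.ravel(), g_a.ravel()])
    else:
        grad = np.concatenate([g_beta1.ravel(), g_a.ravel(), g_gamma.ravel()])
    return obj, grad


def _maximize_structural(X, m1, q, beta1, a, gamma, constrained):
    K = m1.shape[1]
    p = X.shape[1] - 1
    x0 = _pack_structural(beta1, a, gamma, constrained)

    def neg(vec):
        o, g = _structural_obj_grad(vec, X, m1, q, K, constrained)
        return -o, -g

    res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                   options={"ftol": 1e-11, "gtol": 1e-9, "maxiter": 500})
    f0, _ = neg(x0)
    vec = res.x if res.fun <= f0 else x0
    return _unpack_structural(vec, K, p, constrained)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _relabel_lta(params: LTAParams, m1: np.ndarray):
    """Canonical ordering by descending day-1 class size, re-referenced logits."""
    K = params.K
    order = np.argsort(-m1.mean(axis=0), kind="stable")
    p = params.beta1.shape[1] - 1
    eta1 = np.vstack([params.beta1, np.zeros((1, 1 + p))])[order]
    beta1 = eta1[:-1] - eta1[-1]
    A = np.hstack([params.trans_intercepts, np.zeros((K, 1))])[order][:, order]
    G = np.vstack([params.gamma, np.zeros((1, p))])[order]
    A = A - A[:, -1][:, None]
    G = G - G[-1]
    return LTAParams(rho=params.rho[:, order, :], beta1=beta1,
                     trans_intercepts=A[:, :-1], gamma=G[:-1],
                     items=params.items, scaler=params.scaler,
                     constrained=params.constrained), order


def lta_em_fit(ordinal: pd.DataFrame, covariates: pd.DataFrame, K: int,
               n_starts: int = 20, seed: int = 0, tol: float = 1e-8,
               max_iter: int = 1000, constrain_covariate_effects: bool = True,
               prob_floor: float = DEFAULT_PROB_FLOOR) -> FitResult:
    """Fit the transition model by EM with multiple random starts.

    The E-step enumerates the K^2 (day-1, day-2) class paths per subject;
    the M-step pools day-1 and day-2 posterior-weighted category counts
    for the shared rho (measurement invariance) and maximizes the logit
    blocks jointly with a quasi-Newton inner step. With the constraint
    flag on, the destination covariate slopes are identified with the
    day-1 membership slopes throughout.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Y3, subjects, items = ordinal_to_arrays(ordinal, days=(1, 2))
    Y1, Y2 = Y3[:, 0, :], Y3[:, 1, :]
    X, scaler = covariates_to_design(covariates, subjects)
    N, J = Y1.shape
    C, p = 3, X.shape[1] - 1
    constrained = constrain_covariate_effects
    onehot1 = np.eye(C)[Y1]
    onehot2 = np.eye(C)[Y2]

    rng_master = np.random.default_rng(seed)
    best = None
    start_lls = []
    for s in range(n_starts):
        rng = np.random.default_rng(rng_master.integers(2**31))
        rho = rng.dirichlet(np.ones(C), size=(J, K))
        beta1 = rng.normal(scale=0.1, size=(K - 1, 1 + p))
        a = rng.normal(scale=0.5, size=(K, K - 1))
        gamma = beta1[:, 1:].copy() if constrained else rng.normal(scale=0.1,
                                                                   size=(K - 1, p))
        params = LTAParams(rho, beta1, a, gamma, list(items), scaler, constrained)
        trace, warns = [], []
        ll_prev = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            q, ll, _, _ = _e_step(params, Y1, Y2, X, prob_floor)
            trace.append(ll)
            if it > 1 and ll - ll_prev < tol * (abs(ll_prev) + 1.0):
                converged = True
                break
            ll_prev = ll
            m1 = q.sum(axis=2)
            m2 = q.sum(axis=1)
            counts = (np.einsum("ik,ijc->jkc", m1, onehot1)
                      + np.einsum("ik,ijc->jkc", m2, onehot2))
            rho = counts / np.clip(counts.sum(axis=2, keepdims=True), 1e-300, None)
            if np.any(m1.sum(axis=0) < prob_floor * N):
                warns.append(f"near-empty day-1 class at iteration {it}")
            if K > 1:
                beta1, a, gamma = _maximize_structural(
                    X, m1, q, params.beta1, params.trans_intercepts,
                    params.gamma, constrained)
            params = LTAParams(rho, beta1, a, gamma, list(items), scaler, constrained)
        start_lls.append(ll)
        if best is None or ll > best[1]:
            best = (params, ll, q, converged, it, trace, warns)

    params, ll, q, converged, n_iter, trace, warns = best
    if not converged:
        warns = warns + ["EM did not converge within max_iter"]
    m1 = q.sum(axis=2)
    params, order = _relabel_lta(params, m1)
    q = q[:, order][:, :, order]
    m1 = q.sum(axis=2)
    m2 = q.sum(axis=1)

    n_par = count_params("lta", K=K, J=J, C=C, n_covariates=p,
                         constrained=constrained)
    aic, bic = information_criteria(ll, n_par, N)
    ent = relative_entropy(m1)
    return FitResult(params=params, loglik=ll, aic=aic, bic=bic,
                     relative_entropy=ent, n_params=n_par, posterior=m1,
                     modal=classify_modal(m1), converged=converged,
                     n_iter=n_iter, seed=seed, start_logliks=start_lls,
                     best_start=int(np.argmax(start_lls)), loglik_trace=trace,
                     subjects=subjects, warnings=warns,
                     joint_posterior=q, posterior_day2=m2)


# ---------------------------------------------------------------------------
# Transition-matrix summaries
# ---------------------------------------------------------------------------

def transition_matrix(params: LTAParams, age: float, sex: float) -> np.ndarray:
    """K x K row-stochastic transition matrix at a single covariate value."""
    return transition_matrix_grid(params, [age], [sex])[0]


def transition_matrix_grid(params: LTAParams, ages, sexes) -> np.ndarray:
    """Vectorized transition matrices over a covariate grid -> (n, K, K)."""
    if params.scaler is None:
        raise ValueError("params carry no covariate scaler")
    X = params.scaler.design(ages, sexes)
    return np.exp(params.log_transition(X))


def aggregate_transition_matrix(fit: FitResult, covariates: pd.DataFrame) -> np.ndarray:
    """Cohort-level transition matrix.

    Row k averages the subjects' individual transition rows weighted by
    each subject's day-1 posterior membership in class k — the population
    summary printed alongside the fitted model.
    """
    params: LTAParams = fit.params
    subjects = fit.subjects
    if len(subjects) == 0:
        raise ValueError("empty cohort")
    X = _design_for(params, covariates, subjects)
    T = np.exp(params.log_transition(X))  # (N, K, K)
    w = fit.posterior  # (N, K)
    num = np.einsum("ik,ikl->kl", w, T)
    return num / w.sum(axis=0)[:, None]


# ---------------------------------------------------------------------------
# Standard errors and odds ratios for the membership logit
# ---------------------------------------------------------------------------

def _pack_all(params: LTAParams):
    """Unconstrained free-parameter vector (rho as reference-category logits)."""
    eps = 1e-12
    r = np.log(np.clip(params.rho[:, :, :-1], eps, None) /
               np.clip(params.rho[:, :, -1:], eps, None))
    parts = [r.ravel(), params.beta1.ravel(), params.trans_intercepts.ravel()]
    if not params.constrained:
        parts.append(params.gamma.ravel())
    return np.concatenate(parts)


def _unpack_all(vec, J, K, C, p, constrained, items, scaler):
    n_r = J * K * (C - 1)
    r = vec[:n_r].reshape(J, K, C - 1)
    rho = np.exp(log_softmax_ref(r))
    rest = vec[n_r:]
    beta1, a, gamma = _unpack_structural(rest, K, p, constrained)
    return LTAParams(rho, beta1, a, gamma, items, scaler, constrained)


def packed_loglik_grad(vec: np.ndarray, Y1, Y2, X, J, K, C, p, constrained,
                       items, scaler, prob_floor=DEFAULT_PROB_FLOOR):
    """Observed log-likelihood and its analytic gradient in packed coordinates.

    The gradient uses the EM (Fisher) identity: the score of the observed
    likelihood equals the posterior-expected complete-data score.
    """
    params = _unpack_all(vec, J, K, C, p, constrained, items, scaler)
    q, ll, logpi, logT = _e_step(params, Y1, Y2, X, prob_floor)
    m1 = q.sum(axis=2)
    m2 = q.sum(axis=1)

    onehot1 = np.eye(C)[Y1]
    onehot2 = np.eye(C)[Y2]
    w_counts = (np.einsum("ik,ijc->jkc", m1, onehot1)
                + np.einsum("ik,ijc->jkc", m2, onehot2))
    w_tot = w_counts.sum(axis=2, keepdims=True)
    g_r = (w_counts - w_tot * params.rho)[:, :, : C - 1]

    resid_pi = m1 - np.exp(logpi)
    g_beta1 = resid_pi[:, : K - 1].T @ X
    resid_T = q - m1[:, :, None] * np.exp(logT)
    g_a = resid_T[:, :, : K - 1].sum(axis=0)
    g_gamma = np.einsum("ikl,ip->lp", resid_T[:, :, : K - 1], X[:, 1:])
    if constrained:
        g_beta1 = g_beta1.copy()
        g_beta1[:, 1:] += g_gamma
        grad = np.concatenate([g_r.ravel(), g_beta1.ravel(), g_a.ravel()])
    else:
        grad = np.concatenate([g_r.ravel(), g_beta1.ravel(), g_a.ravel(),
                               g_gamma.ravel()])
    return ll, grad


def observed_information(fit: FitResult, ordinal: pd.DataFrame,
                         covariates: pd.DataFrame, step: float = 1e-5) -> np.ndarray:
    """Observed information matrix by central differencing of the score."""
    params: LTAParams = fit.params
    Y3, subjects, items = ordinal_to_arrays(ordinal, days=(1, 2))
    Y1, Y2 = Y3[:, 0, :], Y3[:, 1, :]
    X = _design_for(params, covariates, subjects)
    J, K, C = params.rho.shape
    p = params.beta1.shape[1] - 1
    vec = _pack_all(params)
    n = len(vec)
    H = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        _, gp = packed_loglik_grad(vec + e, Y1, Y2, X, J, K, C, p,
                                   params.constrained, params.items, params.scaler)
        _, gm = packed_loglik_grad(vec - e, Y1, Y2, X, J, K, C, p,
                                   params.constrained, params.items, params.scaler)
        H[i] = (gp - gm) / (2 * step)
    H = 0.5 * (H + H.T)
    return -H


def membership_odds_ratios(fit: FitResult, ordinal: pd.DataFrame,
                           covariates: pd.DataFrame, alpha: float = 0.05,
                           n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Odds ratios (with Wald CIs) for age and sex in the day-1 membership logit.

    Each non-reference class k gets exp(beta1[k, age]) per year of age and
    exp(beta1[k, sex]) for the non-reference sex, versus the last
    (reference) class. Standard errors come from the inverse observed
    information; if that matrix is singular or yields an invalid variance
    a nonparametric bootstrap over subjects is used instead.
    """
    from scipy.stats import norm

    params: LTAParams = fit.params
    K = params.K
    p = params.beta1.shape[1] - 1
    J, C = params.J, params.rho.shape[2]
    n_r = J * K * (C - 1)
    idx_beta1 = np.arange(n_r, n_r + (K - 1) * (1 + p)).reshape(K - 1, 1 + p)

    se = None
    method = "observed_information"
    try:
        info = observed_information(fit, ordinal, covariates)
        cov = np.linalg.inv(info)
        var = np.diag(cov)[idx_beta1.ravel()].reshape(K - 1, 1 + p)
        if np.any(var <= 0) or not np.all(np.isfinite(var)):
            raise np.linalg.LinAlgError("non-positive variance")
        se = np.sqrt(var)
    except np.linalg.LinAlgError:
        import warnings as _w

        _w.warn("observed information singular; falling back to bootstrap",
                stacklevel=2)
        method = "bootstrap"
        se = _bootstrap_se(fit, ordinal, covariates, n_boot, seed)

    z = norm.ppf(1 - alpha / 2)
    age_sd = params.scaler.age_sd if params.scaler is not None else 1.0
    scale = np.array([1.0, 1.0 / age_sd, 1.0])  # intercept, per-year age, sex
    rows = []
    names = ["intercept", "age_per_year", "sex"]
    for k in range(K - 1):
        for jdx, name in enumerate(names):
            if name == "intercept":
                continue
            coef = params.beta1[k, jdx] * scale[jdx]
            s = se[k, jdx] * scale[jdx]
            rows.append({"class": k + 1, "reference_class": K, "covariate": name,
                         "coef": coef, "se": s, "or": float(np.exp(coef)),
                         "ci_low": float(np.exp(coef - z * s)),
                         "ci_high": float(np.exp(coef + z * s)),
                         "method": method})
    return pd.DataFrame(rows)


def _bootstrap_se(fit: FitResult, ordinal: pd.DataFrame, covariates: pd.DataFrame,
                  n_boot: int, seed: int) -> np.ndarray:
    """Nonparametric bootstrap SEs of beta1 (resampling subjects, short refits)."""
    params: LTAParams = fit.params
    rng = np.random.default_rng(seed)
    subjects = np.asarray(fit.subjects)
    draws = []
    for b in range(n_boot):
        samp = rng.choice(subjects, size=len(subjects), replace=True)
        frames = []
        for i, s in enumerate(samp):
            sub = ordinal[ordinal["subject_id"] == s].copy()
            sub["subject_id"] = f"b{i}"
            frames.append(sub)
        boot_ord = pd.concat(frames, ignore_index=True)
        cov = covariates.drop_duplicates("subject_id").set_index("subject_id")
        boot_cov = cov.loc[samp].reset_index(drop=True)
        boot_cov.insert(0, "subject_id", [f"b{i}" for i in range(len(samp))])
        refit = lta_em_fit(boot_ord, boot_cov, K=params.K, n_starts=1,
                           seed=int(rng.integers(2**31)), max_iter=200,
                           constrain_covariate_effects=params.constrained)
        draws.append(refit.params.beta1)
    return np.std(np.stack(draws), axis=0, ddof=1)
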