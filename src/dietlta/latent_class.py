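"""Latent class model for ordinal food-group indicators with concomitant covariates.

The model: each subject belongs to one of K latent dietary patterns; class
membership follows a multinomial logit on age and sex (the concomitant
variables); given the class, the J ordinal indicators are independent with
class-specific category probabilities rho[j, k, c]. With three observed
categories an unrestricted per-class categorical distribution is saturated
with respect to a cumulative-threshold (ordered) parameterization, so rho
is parameterized directly.

Estimation is by EM with multiple random starts; the best solution is
relabeled canonically by descending class size so results do not depend on
start order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._arrays import CovariateScaler, covariates_to_design, ordinal_to_arrays
from ._logit import log_softmax_ref, weighted_multinomial_logit
from .model_selection import count_params, information_criteria, relative_entropy

logger = logging.getLogger(__name__)

DEFAULT_PROB_FLOOR = 1e-6


@dataclass
class LCAParams:
    """Parameters of a fitted (or hand-set) latent class model.

    rho : (J, K, C) item-response probabilities, simplex over the last axis.
    beta : (K-1, 1+p) membership-logit coefficients on (1, z_age, sex);
        the last class is the reference.
    items : food-group names matching rho's first axis.
    scaler : the age standardization used to build the design matrix.
    """

    rho: np.ndarray
    beta: np.ndarray
    items: list[str]
    scaler: CovariateScaler | None = None

    @property
    def K(self) -> int:
        return self.rho.shape[1]

    @property
    def J(self) -> int:
        return self.rho.shape[0]

    @property
    def C(self) -> int:
        return self.rho.shape[2]

    def validate(self, atol: float = 1e-10) -> None:
        if np.any(self.rho < 0) or np.any(self.rho > 1):
            raise ValueError("rho outside [0, 1]")
        if not np.allclose(self.rho.sum(axis=2), 1.0, atol=atol):
            raise ValueError("rho rows do not sum to 1")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta not finite")

    def membership_probs(self, X: np.ndarray) -> np.ndarray:
        """P(C = k | x) for design rows X, shape (N, K)."""
        return np.exp(log_softmax_ref(X @ self.beta.T))

    def to_dict(self) -> dict:
        return {
            "model": "lca",
            "rho": self.rho.tolist(),
            "beta": self.beta.tolist(),
            "items": list(self.items),
            "age_mean": None if self.scaler is None else self.scaler.age_mean,
            "age_sd": None if self.scaler is None else self.scaler.age_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCAParams":
        scaler = None
        if d.get("age_mean") is not None:
            scaler = CovariateScaler(d["age_mean"], d["age_sd"])
        return cls(rho=np.asarray(d["rho"], dtype=float),
                   beta=np.asarray(d["beta"], dtype=float),
                   items=list(d["items"]), scaler=scaler)


@dataclass
class FitResult:
    """Everything a fitted latent model reports.

    ``posterior`` holds day-1 (or single-occasion) class posteriors; for
    transition models ``joint_posterior`` (N, K, K) and ``posterior_day2``
    are filled in as well.
    """

    params: object
    loglik: float
    aic: float
    bic: float
    relative_entropy: float
    n_params: int
    posterior: np.ndarray
    modal: np.ndarray
    converged: bool
    n_iter: int
    seed: int | None
    start_logliks: list[float]
    best_start: int
    loglik_trace: list[float]
    subjects: np.ndarray
    warnings: list[str] = field(default_factory=list)
    joint_posterior: np.ndarray | None = None
    posterior_day2: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.posterior.shape[1]


def _log_emissions(rho: np.ndarray, Y: np.ndarray, prob_floor: float) -> np.ndarray:
    """log prod_j rho[j, k, Y[i, j]] for every subject i and class k -> (N, K)."""
    lr = np.log(np.clip(rho, prob_floor, None))
    N, J = Y.shape
    out = np.zeros((N, lr.shape[1]))
    for j in range(J):
        out += lr[j].T[Y[:, j]]  # (C, K) rows indexed by observed category
    return out


def _posterior_arrays(params: LCAParams, Y: np.ndarray, X: np.ndarray,
                      prob_floor: float = DEFAULT_PROB_FLOOR):
    logprior = log_softmax_ref(X @ params.beta.T)
    logp = logprior + _log_emissions(params.rho, Y, prob_floor)
    ll_i = logsumexp(logp, axis=1)
    post = np.exp(logp - ll_i[:, None])
    return post, float(ll_i.sum())


def lca_loglik(params: LCAParams, ordinal: pd.DataFrame, covariates: pd.DataFrame,
               prob_floor: float = DEFAULT_PROB_FLOOR) -> float:
    """Observed-data log-likelihood of a single-occasion ordinal table.

    Item-response probabilities below ``prob_floor`` are clipped so an
    exact zero at an observed category yields a large negative penalty
    instead of -inf.
    """
    Y, subjects, items = ordinal_to_arrays(ordinal, days=(1,))
    if list(items) != list(params.items):
        raise ValueError(f"items mismatch: params {params.items} vs data {items}")
    if params.scaler is not None:
        cov = covariates.drop_duplicates("subject_id").set_index("subject_id").loc[subjects]
        X = params.scaler.design(cov["age"].to_numpy(float), cov["sex"].to_numpy(float))
    else:
        X, _ = covariates_to_design(covariates, subjects)
    _, ll = _posterior_arrays(params, Y[:, 0, :], X, prob_floor)
    return ll


def _random_start(rng: np.random.Generator, J: int, K: int, C: int, p: int) -> tuple:
    rho = rng.dirichlet(np.ones(C), size=(J, K))
    beta = rng.normal(scale=0.1, size=(K - 1, 1 + p))
    return rho, beta


def _relabel_by_size(rho, beta, post):
    """Order classes by descending posterior size; re-reference the logit."""
    K = rho.shape[1]
    order = np.argsort(-post.mean(axis=0), kind="stable")
    eta_full = np.vstack([beta, np.zeros((1, beta.shape[1]))])  # K x (1+p)
    eta_perm = eta_full[order]
    beta_new = eta_perm[:-1] - eta_perm[-1]
    return rho[:, order, :], beta_new, order


def _em_single(Y, X, K, rng, tol, max_iter, prob_floor):
    N, J = Y.shape
    C = 3
    p = X.shape[1] - 1
    rho, beta = _random_start(rng, J, K, C, p)
    onehot = np.eye(C)[Y]  # (N, J, C)
    trace = []
    ll_prev = -np.inf
    converged = False
    warns = []
    for it in range(1, max_iter + 1):
        logprior = log_softmax_ref(X @ beta.T)
        logp = logprior + _log_emissions(rho, Y, prob_floor)
        ll_i = logsumexp(logp, axis=1)
        ll = float(ll_i.sum())
        post = np.exp(logp - ll_i[:, None])
        trace.append(ll)
        if ll - ll_prev < tol * (abs(ll_prev) + 1.0) and it > 1:
            converged = True
            break
        ll_prev = ll
        # M-step
        mass = post.sum(axis=0)  # (K,)
        if np.any(mass < prob_floor * N):
            warns.append(f"near-empty class at iteration {it}")
        counts = np.einsum("ik,ijc->jkc", post, onehot)
        rho = counts / np.clip(counts.sum(axis=2, keepdims=True), 1e-300, None)
        if K > 1:
            beta = weighted_multinomial_logit(X, post, beta0=beta)
    return rho, beta, ll, post, converged, it, trace, warns


def lca_em_fit(ordinal: pd.DataFrame, covariates: pd.DataFrame, K: int,
               n_starts: int = 20, seed: int = 0, tol: float = 1e-8,
               max_iter: int = 1000,
               prob_floor: float = DEFAULT_PROB_FLOOR) -> FitResult:
    """Fit a K-class model by EM over ``n_starts`` random initializations.

    The returned fit carries the best start's solution, relabeled so
    classes come in descending size order, together with per-start
    log-likelihoods and the per-iteration trace of the winning start.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    Y3, subjects, items = ordinal_to_arrays(ordinal, days=(1,))
    Y = Y3[:, 0, :]
    X, scaler = covariates_to_design(covariates, subjects)
    N = len(subjects)

    rng_master = np.random.default_rng(seed)
    best = None
    start_lls = []
    for s in range(n_starts):
        rng = np.random.default_rng(rng_master.integers(2**31))
        result = _em_single(Y, X, K, rng, tol, max_iter, prob_floor)
        start_lls.append(result[2])
        if best is None or result[2] > best[0][2]:
            best = (result, s)
    (rho, beta, ll, post, converged, n_iter, trace, warns), best_start = best
    if not converged:
        warns = warns + ["EM did not converge within max_iter"]

    rho, beta, order = _relabel_by_size(rho, beta, post)
    params = LCAParams(rho=rho, beta=beta, items=list(items), scaler=scaler)
    post = post[:, order]

    n_par = count_params("lca", K=K, J=len(items), C=3, n_covariates=X.shape[1] - 1)
    aic, bic = information_criteria(ll, n_par, N)
    ent = relative_entropy(post)
    modal = classify_modal(post)
    return FitResult(params=params, loglik=ll, aic=aic, bic=bic,
                     relative_entropy=ent, n_params=n_par, posterior=post,
                     modal=modal, converged=converged, n_iter=n_iter, seed=seed,
                     start_logliks=start_lls, best_start=best_start,
                     loglik_trace=trace, subjects=subjects, warnings=warns)


def lca_posterior(params: LCAParams, ordinal: pd.DataFrame,
                  covariates: pd.DataFrame,
                  prob_floor: float = DEFAULT_PROB_FLOOR) -> np.ndarray:
    """Posterior class-membership matrix (subjects x K), rows summing to 1."""
    Y, subjects, items = ordinal_to_arrays(ordinal, days=(1,))
    if list(items) != list(params.items):
        raise ValueError("items mismatch between params and data")
    if params.scaler is not None:
        cov = covariates.drop_duplicates("subject_id").set_index("subject_id").loc[subjects]
        X = params.scaler.design(cov["age"].to_numpy(float), cov["sex"].to_numpy(float))
    else:
        X, _ = covariates_to_design(covariates, subjects)
    post, _ = _posterior_arrays(params, Y[:, 0, :], X, prob_floor)
    return post


def classify_modal(posterior: np.ndarray) -> np.ndarray:
    """Modal class per subject (argmax posterior); ties go to the lowest index."""
    posterior = np.asarray(posterior)
    labels = posterior.argmax(axis=1)
    row_max = posterior.max(axis=1, keepdims=True)
    n_tied = int(np.sum((posterior == row_max).sum(axis=1) > 1))
    if n_tied:
        logger.info("modal assignment: %d tie(s) broken toward the lowest class index",
                    n_tied)
    return labels


def class_profile_table(ordinal: pd.DataFrame, weights: np.ndarray,
                        day: int = 1) -> pd.DataFrame:
    """Class-conditional category percentages per food group.

    ``weights`` is either a (N, K) posterior matrix (posterior-weighted
    profile) or a length-N integer label vector (hard crosstab). Returns a
    tidy frame with columns item, class, pct_nil, pct_below_median,
    pct_above_median; the three percentages sum to 100 per row.
    """
    Y3, subjects, items = ordinal_to_arrays(ordinal, days=(day,))
    Y = Y3[:, 0, :]
    weights = np.asarray(weights)
    if weights.ndim == 1:
        K = int(weights.max()) + 1
        W = np.eye(K)[weights.astype(int)]
    else:
        W = weights
    K = W.shape[1]
    onehot = np.eye(3)[Y]  # (N, J, C)
    counts = np.einsum("ik,ijc->kjc", W, onehot)
    pct = 100.0 * counts / counts.sum(axis=2, keepdims=True)
    rows = []
    for k in range(K):
        for j, item in enumerate(items):
            rows.append({"item": item, "class": k + 1,
                         "pct_nil": pct[k, j, 0],
                         "pct_below_median": pct[k, j, 1],
                         "pct_above_median": pct[k, j, 2]})
    return pd.DataFrame(rows)
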