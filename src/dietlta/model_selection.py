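"""Fit indices, free-parameter counting, and the class-number sweep.

The number of dietary patterns is not known a priori: models with a range
of class counts are fitted under a shared random-start protocol and
compared on AIC, BIC, log-likelihood and relative entropy. The automatic
choice is the BIC minimum; the full table is returned so the analyst can
weigh the criteria qualitatively.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = -2 LL + 2 p and BIC = -2 LL + p ln N."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * math.log(n_obs)
    return aic, bic


def relative_entropy(posterior: np.ndarray) -> float:
    """Normalized classification certainty in [0, 1].

    1 - sum_i sum_k (-p_ik ln p_ik) / (N ln K): 1 means every subject is
    assigned with certainty, 0 means posteriors are uniform. For K = 1
    there is no classification uncertainty and the value is defined as 1
    (with a warning).
    """
    posterior = np.asarray(posterior, dtype=float)
    N, K = posterior.shape
    if K == 1:
        warnings.warn("relative entropy with K=1 is degenerate; returning 1",
                      stacklevel=2)
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(posterior > 0, posterior * np.log(posterior), 0.0)
    return 1.0 + float(plogp.sum()) / (N * math.log(K))


def count_params(model: str, K: int, J: int, C: int = 3, n_covariates: int = 2,
                 constrained: bool = True) -> int:
    """Free parameters of the categorical-indicator latent models.

    lca: J*K*(C-1) item-response parameters plus (K-1)*(1+p) membership
    logits. lta adds K*(K-1) transition intercepts; with the covariate
    effects unconstrained it further adds (K-1)*p destination slopes
    (constrained fits share those slopes with the day-1 membership logit).
    """
    p = n_covariates
    rho = J * K * (C - 1)
    membership = (K - 1) * (1 + p)
    if model == "lca":
        return rho + membership
    if model == "lta":
        extra = 0 if constrained else (K - 1) * p
        return rho + membership + K * (K - 1) + extra
    raise ValueError(f"unknown model type {model!r}")


def fit_grid(ordinal: pd.DataFrame, covariates: pd.DataFrame, model: str,
             K_range, n_starts: int = 20, seed: int = 0,
             **fit_kwargs) -> tuple[pd.DataFrame, object]:
    """Fit every K in ``K_range`` and tabulate the criteria.

    Returns (SelectionTable, fit of the BIC-minimizing K). Each K gets its
    own deterministic sub-seed derived from ``seed``. A K that fails to
    converge stays in the table flagged, never silently dropped.
    """
    from .latent_class import lca_em_fit
    from .latent_transition import lta_em_fit

    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range is empty")
    fitters = {"lca": lca_em_fit, "lta": lta_em_fit}
    if model not in fitters:
        raise ValueError(f"unknown model type {model!r}")

    rows, fits = [], {}
    for K in K_range:
        sub_seed = int(np.random.default_rng([seed, K]).integers(2**31))
        fit = fitters[model](ordinal, covariates, K, n_starts=n_starts,
                             seed=sub_seed, **fit_kwargs)
        fits[K] = fit
        rows.append({"model": model, "K": K, "loglik": fit.loglik,
                     "n_params": fit.n_params, "aic": fit.aic, "bic": fit.bic,
                     "relative_entropy": fit.relative_entropy,
                     "converged": fit.converged, "seed": sub_seed})
    table = pd.DataFrame(rows)
    best_K = int(table.loc[table["bic"].idxmin(), "K"])
    table["selected"] = table["K"] == best_K
    return table, fits[best_K]
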