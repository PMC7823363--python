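"""Multinomial-logistic (softmax) utilities shared by the latent models.

All membership and transition submodels are multinomial logits with the
*last* category fixed as reference (linear predictor identically zero).
Coefficient blocks therefore have shape ``(K-1, p)`` for K categories and
p regressors.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def log_softmax_ref(eta: np.ndarray) -> np.ndarray:
    """Log-probabilities of a softmax with an implicit zero reference column.

    Parameters
    ----------
    eta : (..., K-1) array of linear predictors for the non-reference
        categories. A zero column is appended for the reference (last)
        category before normalization.

    Returns
    -------
    (..., K) array of log-probabilities summing to 1 on the last axis.
    """
    eta_full = np.concatenate([eta, np.zeros(eta.shape[:-1] + (1,))], axis=-1)
    return eta_full - logsumexp(eta_full, axis=-1, keepdims=True)


def softmax_ref(eta: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax_ref(eta))


def weighted_multinomial_logit(
    X: np.ndarray,
    W: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """Maximize ``sum_i sum_k W[i,k] * log softmax_k(X[i] @ beta)``.

    X : (N, p) design matrix (include an intercept column explicitly).
    W : (N, K) non-negative weights; rows need not sum to 1.
    beta0 : (K-1, p) warm start; zeros if omitted.

    Returns the (K-1, p) coefficient block (reference = last category).
    The returned objective is never worse than the warm start's, so an EM
    M-step using this routine preserves the ascent property.
    """
    N, p = X.shape
    K = W.shape[1]
    if K == 1:
        return np.zeros((0, p))
    if beta0 is None:
        beta0 = np.zeros((K - 1, p))

    def negobj_grad(vec: np.ndarray):
        beta = vec.reshape(K - 1, p)
        logpi = log_softmax_ref(X @ beta.T)  # (N, K)
        obj = float(np.sum(W * logpi))
        resid = W - W.sum(axis=1, keepdims=True) * np.exp(logpi)  # (N, K)
        grad = resid[:, : K - 1].T @ X  # (K-1, p)
        return -obj, -grad.ravel()

    res = minimize(negobj_grad, beta0.ravel(), jac=True, method="L-BFGS-B",
                   options={"ftol": tol, "gtol": 1e-9, "maxiter": 500})
    f0, _ = negobj_grad(beta0.ravel())
    if res.fun <= f0:
        return res.x.reshape(K - 1, p)
    return beta0.copy()
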