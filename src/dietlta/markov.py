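"""Markov-chain machinery behind the usual prevalence of dietary patterns.

With day-to-day pattern changes modeled as a first-order Markov chain,
the day-d state distribution is S_d = S_1 P^{d-1}. If P is regular (some
power strictly positive), S_d converges to the unique stationary vector
S_inf, the *usual prevalence*: the long-run share of days spent in each
dietary pattern. Because the fitted transitions are covariate-conditional,
the cohort usual prevalence can be formed either by averaging per-subject
stationary vectors (default) or by taking the stationary vector of the
cohort-aggregated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class NotRegularError(ValueError):
    """The transition matrix has no strictly positive power within the bound."""


def _check_transition(P: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < -atol) or np.any(P > 1 + atol):
        raise ValueError("transition probabilities outside [0, 1]")
    if not np.allclose(P.sum(axis=1), 1.0, atol=atol):
        raise ValueError("transition-matrix rows must sum to 1")
    return P


def _check_state(S: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 1:
        raise ValueError("state vector must be one-dimensional")
    if np.any(S < -atol) or not np.isclose(S.sum(), 1.0, atol=atol):
        raise ValueError("state vector must be a probability vector")
    return S


def is_regular(P: np.ndarray, max_power: int | None = None) -> tuple[bool, int | None]:
    """Whether some power of P up to ``max_power`` is strictly positive.

    Returns ``(regular, certifying_power)``. The default bound
    (K-1)^2 + 1 is the Wielandt primitivity bound: a primitive matrix
    must show a strictly positive power by then.
    """
    P = _check_transition(P)
    K = P.shape[0]
    if max_power is None:
        max_power = (K - 1) ** 2 + 1
    M = np.eye(K)
    for m in range(1, max_power + 1):
        M = M @ P
        if np.all(M > 0):
            return True, m
    return False, None


def propagate(S1: np.ndarray, P: np.ndarray, d: int) -> np.ndarray:
    """State distribution at day d: S_d = S_1 P^{d-1}; d = 1 returns S_1."""
    S = _check_state(S1)
    P = _check_transition(P)
    if d < 1:
        raise ValueError("d must be >= 1")
    return S @ np.linalg.matrix_power(P, d - 1)


def stationary(P: np.ndarray, tol: float = 1e-12, max_iter: int = 1_000_000) -> np.ndarray:
    """Unique stationary vector of a regular transition matrix.

    Power iteration from the uniform vector until successive iterates
    differ by less than ``tol`` in max-norm, cross-checked against the
    leading left eigenvector; a non-regular matrix raises instead of
    silently returning a non-converged limit.
    """
    P = _check_transition(P)
    regular, power = is_regular(P)
    if not regular:
        raise NotRegularError(
            "transition matrix is not regular (no strictly positive power within "
            f"the Wielandt bound {(P.shape[0] - 1) ** 2 + 1}); "
            "the stationary distribution is not unique/attracting")
    K = P.shape[0]
    S = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        S_new = S @ P
        if np.max(np.abs(S_new - S)) < tol:
            S = S_new
            break
        S = S_new
    S = S / S.sum()
    # internal cross-check against the eigen-decomposition route
    w, v = np.linalg.eig(P.T)
    lead = np.argmin(np.abs(w - 1.0))
    S_eig = np.real(v[:, lead])
    S_eig = S_eig / S_eig.sum()
    if np.max(np.abs(S - S_eig)) > 1e-6:  # pragma: no cover
        raise RuntimeError("power iteration and eigenvector stationary disagree")
    return S


@dataclass
class UsualPrevalenceResult:
    """Cohort usual prevalence alongside the single-day state vectors."""

    usual: np.ndarray          # S_inf (cohort)
    s1: np.ndarray             # day-1 state vector (mean day-1 posterior)
    s2: np.ndarray             # day-2 state vector
    mode: str
    per_subject: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        K = len(self.usual)
        return pd.DataFrame({
            "class": np.arange(1, K + 1),
            "day1": self.s1, "day2": self.s2, "usual": self.usual,
        })


def usual_prevalence(fit, covariates: pd.DataFrame, mode: str = "individual"
                     ) -> UsualPrevalenceResult:
    """Usual (long-run) prevalence of the dietary patterns in a cohort.

    individual mode (default): per-subject stationary vectors of the
    covariate-conditional transition matrices, averaged over subjects.
    aggregate mode: stationary vector of the cohort-aggregated matrix.
    The two agree exactly when all subjects share one covariate value.
    """
    from .latent_transition import (_design_for, aggregate_transition_matrix)

    params = fit.params
    if mode not in ("individual", "aggregate"):
        raise ValueError("mode must be 'individual' or 'aggregate'")
    s1 = fit.posterior.mean(axis=0)
    s2 = fit.posterior_day2.mean(axis=0)

    if mode == "aggregate":
        P = aggregate_transition_matrix(fit, covariates)
        return UsualPrevalenceResult(usual=stationary(P), s1=s1, s2=s2, mode=mode)

    X = _design_for(params, covariates, fit.subjects)
    T = np.exp(params.log_transition(X))  # (N, K, K)
    non_regular = []
    rows = []
    for i, subject in enumerate(fit.subjects):
        ok, _ = is_regular(T[i])
        if not ok:
            non_regular.append(subject)
            continue
        rows.append(stationary(T[i]))
    if non_regular:
        raise NotRegularError(
            f"non-regular individual transition matrices for subjects "
            f"{non_regular[:10]}{'...' if len(non_regular) > 10 else ''}")
    per = np.vstack(rows)
    detail = pd.DataFrame(per, columns=[f"class_{k + 1}" for k in range(per.shape[1])])
    detail.insert(0, "subject_id", fit.subjects)
    return UsualPrevalenceResult(usual=per.mean(axis=0), s1=s1, s2=s2,
                                 mode=mode, per_subject=detail)
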