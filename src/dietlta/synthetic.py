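"""Synthetic two-day dietary-recall cohorts with known latent structure.

The generator draws covariates (age, sex), a day-1 dietary-pattern class
from a multinomial logit on those covariates, a day-2 class from the
covariate-conditional transition row of the day-1 class, and ordinal
food-group indicators from class-conditional category probabilities. An
optional continuous layer instead draws gram amounts (zero-inflated gamma)
so that the median-based ordinal coding in :mod:`dietlta.data_prep` is
exercised rather than bypassed, and food-group zero inflation and
day-to-day variability emerge naturally.

Every draw descends from one master seed through a spawned seed sequence,
so the same (config, seed) pair always regenerates the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._arrays import CovariateScaler
from ._logit import log_softmax_ref
from .markov import NotRegularError, is_regular, stationary


@dataclass
class GeneratorConfig:
    """Ground truth for a simulated cohort.

    Logit coefficients act on the design ``(1, z_age, sex)`` where
    ``z_age`` standardizes age by the theoretical mean and SD of the
    uniform age distribution on ``age_range``. ``sex`` is 1 with
    probability ``sex1_proportion`` (reference category 0).
    """

    n_subjects: int
    rho: np.ndarray                      # (J, K, C)
    beta1: np.ndarray                    # (K-1, 3): intercept, z_age, sex
    trans_intercepts: np.ndarray         # (K, K-1)
    gamma: np.ndarray                    # (K-1, 2): z_age, sex
    items: list[str] | None = None
    age_range: tuple[float, float] = (18.0, 84.0)
    sex1_proportion: float = 0.47
    # optional continuous-intake layer
    consumption_prob: np.ndarray | None = None   # (J, K)
    amount_shape: np.ndarray | None = None       # (J,)
    amount_scale: np.ndarray | None = None       # (J, K)

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.trans_intercepts = np.asarray(self.trans_intercepts, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.allclose(self.rho.sum(axis=2), 1.0, atol=1e-8):
            raise ValueError("rho rows must be simplices")
        if np.any(self.rho < 0):
            raise ValueError("rho entries must be non-negative")
        if self.items is None:
            self.items = [f"fg{j + 1:02d}" for j in range(self.J)]

    @property
    def J(self) -> int:
        return self.rho.shape[0]

    @property
    def K(self) -> int:
        return self.rho.shape[1]

    @property
    def C(self) -> int:
        return self.rho.shape[2]

    @property
    def scaler(self) -> CovariateScaler:
        lo, hi = self.age_range
        return CovariateScaler(age_mean=(lo + hi) / 2.0,
                               age_sd=(hi - lo) / np.sqrt(12.0))

    @property
    def has_continuous_layer(self) -> bool:
        return self.consumption_prob is not None

    def transition_at(self, age, sex) -> np.ndarray:
        """True covariate-conditional transition matrix, (K, K)."""
        x = self.scaler.design(age, sex)[0, 1:]
        eta = self.trans_intercepts + (self.gamma @ x)[None, :]
        return np.exp(log_softmax_ref(eta))

    def membership_at(self, age, sex) -> np.ndarray:
        X = self.scaler.design(age, sex)
        return np.exp(log_softmax_ref(X @ self.beta1.T))[0]


@dataclass
class SyntheticCohort:
    covariates: pd.DataFrame
    labels_day1: np.ndarray
    labels_day2: np.ndarray
    ordinal: pd.DataFrame
    intake: pd.DataFrame | None
    config: GeneratorConfig
    seed: int


def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """One draw per row of a (N, K) probability matrix."""
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1).clip(max=probs.shape[1] - 1)


def generate_population(config: GeneratorConfig, seed: int) -> SyntheticCohort:
    """Draw a full cohort (covariates, latent classes, indicators) from the truth."""
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_cov, rng_class, rng_emit, rng_amount = (np.random.default_rng(s) for s in ss)

    N, J, K, C = config.n_subjects, config.J, config.K, config.C
    lo, hi = config.age_range
    age = rng_cov.uniform(lo, hi, size=N)
    sex = (rng_cov.random(N) < config.sex1_proportion).astype(int)
    subjects = np.array([f"s{i + 1:05d}" for i in range(N)])
    covariates = pd.DataFrame({"subject_id": subjects, "age": age, "sex": sex})

    X = config.scaler.design(age, sex)
    pi = np.exp(log_softmax_ref(X @ config.beta1.T))  # (N, K)
    c1 = _sample_categorical(rng_class, pi)
    eta_T = config.trans_intercepts[None, :, :] + (X[:, 1:] @ config.gamma.T)[:, None, :]
    T = np.exp(log_softmax_ref(eta_T))  # (N, K, K)
    c2 = _sample_categorical(rng_class, T[np.arange(N), c1])

    intake = None
    if config.has_continuous_layer:
        intake = _draw_amounts(config, rng_amount, subjects, c1, c2)
        from .data_prep import categorize_intake

        ordinal, _ = categorize_intake(intake)
    else:
        frames = []
        for day, labels in ((1, c1), (2, c2)):
            cats = np.empty((N, J), dtype=int)
            for j in range(J):
                cats[:, j] = _sample_categorical(rng_emit, config.rho[j][labels])
            frames.append(pd.DataFrame({
                "subject_id": np.repeat(subjects, J),
                "day": day,
                "item": np.tile(config.items, N),
                "category": cats.ravel(),
            }))
        ordinal = pd.concat(frames, ignore_index=True)

    return SyntheticCohort(covariates=covariates, labels_day1=c1, labels_day2=c2,
                           ordinal=ordinal, intake=intake, config=config, seed=seed)


def _draw_amounts(config, rng, subjects, c1, c2) -> pd.DataFrame:
    """Zero-inflated gamma gram amounts for the continuous layer."""
    N, J = len(subjects), config.J
    frames = []
    for day, labels in ((1, c1), (2, c2)):
        p_cons = config.consumption_prob[:, labels].T  # (N, J)
        consumed = rng.random((N, J)) < p_cons
        shape = np.broadcast_to(config.amount_shape, (N, J))
        scale = config.amount_scale[:, labels].T
        amounts = np.where(consumed, rng.gamma(shape, scale), 0.0)
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(subjects, J),
            "day": day,
            "food_group": np.tile(config.items, N),
            "amount": amounts.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def _covariate_nodes(config: GeneratorConfig, n_age_nodes: int = 41):
    """Gauss-Legendre nodes and weights over the covariate distribution."""
    lo, hi = config.age_range
    x, w = np.polynomial.legendre.leggauss(n_age_nodes)
    ages = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    w_age = w / w.sum()  # uniform density cancels in the normalized weights
    nodes = []
    for sex, p_sex in ((0, 1 - config.sex1_proportion), (1, config.sex1_proportion)):
        for age_i, w_i in zip(ages, w_age):
            nodes.append((age_i, sex, w_i * p_sex))
    return nodes


def true_initial_prevalence(config: GeneratorConfig, n_age_nodes: int = 41) -> np.ndarray:
    """Covariate-averaged day-1 class probabilities implied by the truth."""
    out = np.zeros(config.K)
    for age, sex, w in _covariate_nodes(config, n_age_nodes):
        out += w * config.membership_at(age, sex)
    return out


def true_usual_prevalence(config: GeneratorConfig, n_age_nodes: int = 41) -> np.ndarray:
    """Covariate-averaged stationary vector of the true transition matrices.

    Numerical integration (Gauss-Legendre in age x the two sexes) of the
    per-covariate stationary distribution; the recovery target for
    estimated usual prevalence.
    """
    out = np.zeros(config.K)
    for age, sex, w in _covariate_nodes(config, n_age_nodes):
        P = config.transition_at(age, sex)
        ok, _ = is_regular(P)
        if not ok:
            raise NotRegularError(f"true transition matrix at age={age:.1f}, "
                                  f"sex={sex} is not regular")
        out += w * stationary(P)
    return out


def true_aggregate_transition(config: GeneratorConfig, n_age_nodes: int = 41
                              ) -> np.ndarray:
    """Cohort-level true transition matrix.

    Row k is the covariate-average of the true transition rows weighted by
    the true day-1 membership probability of class k — the population
    counterpart of the aggregate matrix computed from a fitted model.
    """
    K = config.K
    num = np.zeros((K, K))
    den = np.zeros(K)
    for age, sex, w in _covariate_nodes(config, n_age_nodes):
        pi = config.membership_at(age, sex)
        P = config.transition_at(age, sex)
        num += w * pi[:, None] * P
        den += w * pi
    return num / den[:, None]


def paper_like_config(n_subjects: int = 3849, continuous: bool = True,
                      n_items: int = 28) -> GeneratorConfig:
    """A cohort preset mirroring a national two-recall dietary survey.

    Three dietary patterns; 28 food groups with nil fractions spanning
    roughly 10-95 %; diagonal-heavy transitions; age and sex effects with
    the older/female gradient pointing toward the healthier-like third
    pattern. The preset reproduces the *structure* of such a survey, not
    any particular estimate from one.
    """
    rng = np.random.default_rng(20150901)  # fixed: the preset is a constant
    K, C, J = 3, 3, n_items

    nil_base = np.linspace(0.10, 0.93, J)
    rng.shuffle(nil_base)
    rho = np.empty((J, K, C))
    for j in range(J):
        for k in range(K):
            shift = rng.uniform(-0.12, 0.12)
            nil = float(np.clip(nil_base[j] + shift, 0.02, 0.96))
            # class-specific split of the consumer mass between the two
            # intake levels makes the patterns separable
            hi_share = rng.uniform(0.2, 0.8)
            rho[j, k] = [nil, (1 - nil) * (1 - hi_share), (1 - nil) * hi_share]

    # membership: class 3 (healthier-like, reference) favored by older women
    beta1 = np.array([
        [0.35, 0.55, 0.80],   # class 1 vs 3: younger, more male
        [-0.10, 0.90, 0.85],  # class 2 vs 3: youngest, more male
    ])
    # diagonal-heavy transitions, mild exchange between classes 1 and 2
    trans_intercepts = np.array([
        [2.9, 0.9],    # from class 1
        [1.2, 3.0],    # from class 2
        [-1.3, -0.9],  # from class 3 (sticky via small off-diagonal mass)
    ])
    gamma = np.array([
        [0.25, 0.30],
        [0.35, 0.35],
    ])

    kwargs = {}
    if continuous:
        # consumption probability per class from the target nil fractions;
        # class-specific gamma scale shifts the consumer median coding
        kwargs["consumption_prob"] = 1.0 - rho[:, :, 0]
        kwargs["amount_shape"] = rng.uniform(1.2, 3.0, size=J)
        base_scale = rng.uniform(20.0, 120.0, size=J)
        mult = 1.0 + 1.5 * rho[:, :, 2] / np.clip(rho[:, :, 1] + rho[:, :, 2], 1e-9, None)
        kwargs["amount_scale"] = base_scale[:, None] * mult

    return GeneratorConfig(n_subjects=n_subjects, rho=rho, beta1=beta1,
                           trans_intercepts=trans_intercepts, gamma=gamma,
                           **kwargs)
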