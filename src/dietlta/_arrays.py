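"""Conversion between tidy tables and the dense arrays the estimators use."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_prep import DataPrepError


@dataclass(frozen=True)
class CovariateScaler:
    """Internal z-scoring of age for optimizer stability.

    Models are estimated on ``(1, z_age, sex)`` with
    ``z_age = (age - age_mean) / age_sd``; coefficient reports convert the
    age slope back to the per-year scale.
    """

    age_mean: float
    age_sd: float

    def design(self, age, sex) -> np.ndarray:
        """Design rows ``(1, z_age, sex)`` for scalar or vector inputs."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        sex = np.atleast_1d(np.asarray(sex, dtype=float))
        z = (age - self.age_mean) / self.age_sd
        return np.column_stack([np.ones_like(z), z, sex])


def covariates_to_design(
    covariates: pd.DataFrame, subjects: np.ndarray
) -> tuple[np.ndarray, CovariateScaler]:
    """Align a covariate table to a subject order and build the design matrix."""
    for col in ("subject_id", "age", "sex"):
        if col not in covariates.columns:
            raise DataPrepError(f"covariate table missing column {col!r}")
    cov = covariates.drop_duplicates("subject_id").set_index("subject_id")
    missing = [s for s in subjects if s not in cov.index]
    if missing:
        raise DataPrepError(f"covariates missing for subjects {missing[:10]}")
    cov = cov.loc[subjects]
    if not set(np.unique(cov["sex"])) <= {0, 1}:
        raise DataPrepError("sex must be coded 0/1")
    age = cov["age"].to_numpy(dtype=float)
    sd = float(age.std(ddof=0))
    scaler = CovariateScaler(age_mean=float(age.mean()), age_sd=sd if sd > 0 else 1.0)
    return scaler.design(age, cov["sex"].to_numpy(dtype=float)), scaler


def ordinal_to_arrays(
    ordinal: pd.DataFrame, days: tuple[int, ...] = (1,)
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pivot a long ordinal table into a (N, n_days, J) integer array.

    Returns (Y, subjects, items); subjects keep first-appearance order,
    items are sorted for a stable column layout. Every requested day must
    be present for every subject and item.
    """
    for col in ("subject_id", "day", "item", "category"):
        if col not in ordinal.columns:
            raise DataPrepError(f"ordinal table missing column {col!r}")
    sub = ordinal[ordinal["day"].isin(days)]
    subjects = sub["subject_id"].unique()
    items = sorted(sub["item"].unique())
    pivot = sub.pivot_table(index="subject_id", columns=["day", "item"],
                            values="category", aggfunc="first")
    expected = pd.MultiIndex.from_product([days, items])
    try:
        pivot = pivot.reindex(index=subjects, columns=expected)
    except Exception as exc:  # pragma: no cover
        raise DataPrepError(f"could not align ordinal table: {exc}") from exc
    if pivot.isna().any().any():
        raise DataPrepError("ordinal table has missing (subject, day, item) cells")
    Y = pivot.to_numpy(dtype=int).reshape(len(subjects), len(days), len(items))
    if Y.min() < 0 or Y.max() > 2:
        raise DataPrepError("categories must be in {0, 1, 2}")
    return Y, subjects, items
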