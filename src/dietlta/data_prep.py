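"""Preparation of repeated 24 h dietary-recall data for latent modelling.

Raw input is a per-subject, per-day table of food-group intake in grams.
This module filters rarely consumed food groups, collapses the two recall
days to a per-subject mean (for the latent-class branch), codes intake
into three ordinal categories (nil / at-or-below the consumer median /
above the consumer median), and quantifies day-to-day variability through
one-way random-effects intra-class correlation coefficients.

Long tables use columns ``subject_id, day, food_group, amount``; ordinal
tables use ``subject_id, day, item, category``. A record that is absent
from a long table is treated as a nil (zero-gram) day for that food group,
which is how recall software typically exports consumption-only rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTAKE_COLUMNS = ["subject_id", "day", "food_group", "amount"]
ORDINAL_COLUMNS = ["subject_id", "day", "item", "category"]

NIL, BELOW_MEDIAN, ABOVE_MEDIAN = 0, 1, 2


class DataPrepError(ValueError):
    """Raised when an intake or covariate table violates its contract."""


@dataclass
class ExclusionReport:
    """Outcome of the rare-food-group filter."""

    threshold: float
    excluded: dict[str, float] = field(default_factory=dict)  # group -> nil fraction
    retained: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "excluded": self.excluded,
            "retained": self.retained,
        }


def _check_intake(intake: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTAKE_COLUMNS if c not in intake.columns]
    if missing:
        raise DataPrepError(f"intake table missing columns {missing}")
    if len(intake) == 0:
        raise DataPrepError("intake table is empty")
    if (intake["amount"] < 0).any():
        bad = intake.loc[intake["amount"] < 0]
        raise DataPrepError(f"negative amounts for {bad['food_group'].unique().tolist()}")
    dup = intake.duplicated(subset=["subject_id", "day", "food_group"])
    if dup.any():
        raise DataPrepError("duplicate (subject, day, food_group) records")
    days = set(intake["day"].unique())
    if not days <= {1, 2}:
        raise DataPrepError(f"day must be 1 or 2, got {sorted(days)}")
    return intake


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide recall table (one column per food group) to long format."""
    id_cols = ["subject_id", "day"]
    missing = [c for c in id_cols if c not in wide.columns]
    if missing:
        raise DataPrepError(f"wide table missing columns {missing}")
    long = wide.melt(id_vars=id_cols, var_name="food_group", value_name="amount")
    return long[INTAKE_COLUMNS]


def densify(intake: pd.DataFrame) -> pd.DataFrame:
    """Expand to the full subject x day x food-group grid, filling nil days with 0."""
    _check_intake(intake)
    pivot = intake.pivot_table(index=["subject_id", "day"], columns="food_group",
                               values="amount", fill_value=0.0, aggfunc="first")
    subjects = intake["subject_id"].unique()
    days = sorted(intake["day"].unique())
    full_index = pd.MultiIndex.from_product([subjects, days], names=["subject_id", "day"])
    pivot = pivot.reindex(full_index, fill_value=0.0)
    long = pivot.stack().rename("amount").reset_index()
    long.columns = INTAKE_COLUMNS
    return long


def require_complete_cases(intake: pd.DataFrame, drop: bool = True) -> pd.DataFrame:
    """Keep only subjects observed on both recall days.

    With ``drop=False`` an incomplete subject raises instead of being
    removed; with ``drop=True`` the number of dropped subjects is logged
    through :mod:`warnings`.
    """
    days_per_subject = intake.groupby("subject_id")["day"].nunique()
    incomplete = days_per_subject.index[days_per_subject < 2]
    if len(incomplete) == 0:
        return intake
    if not drop:
        raise DataPrepError(f"subjects missing a recall day: {list(incomplete[:10])}")
    warnings.warn(f"dropped {len(incomplete)} subject(s) without both recall days",
                  stacklevel=2)
    return intake[~intake["subject_id"].isin(incomplete)].reset_index(drop=True)


def filter_rare_food_groups(
    intake: pd.DataFrame, nil_fraction_threshold: float = 0.95
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop food groups with nil consumption on at least a given fraction of person-days.

    A group whose nil fraction is greater than **or equal to** the
    threshold is excluded: "nil in 95 % of the days" counts the boundary.

    Returns the filtered long table (dense grid) and an
    :class:`ExclusionReport` mapping each group to its nil fraction.
    """
    if not 0 < nil_fraction_threshold <= 1:
        raise DataPrepError("nil_fraction_threshold must be in (0, 1]")
    dense = densify(intake)
    nil_frac = dense.groupby("food_group")["amount"].apply(lambda a: float((a == 0).mean()))
    report = ExclusionReport(threshold=nil_fraction_threshold)
    for group, frac in nil_frac.items():
        if frac >= nil_fraction_threshold:
            report.excluded[group] = frac
        else:
            report.retained[group] = frac
    if not report.retained:
        raise DataPrepError("all food groups excluded; nothing left to model")
    kept = dense[dense["food_group"].isin(report.retained)].reset_index(drop=True)
    return kept, report


def average_days(intake: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of the two recall days per subject and food group.

    The result is a single pseudo-day table (``day`` column fixed at 1),
    consumed by the latent-class branch of the analysis.
    """
    dense = densify(intake)
    days_per_subject = dense.groupby("subject_id")["day"].nunique()
    incomplete = days_per_subject.index[days_per_subject < 2]
    if len(incomplete):
        raise DataPrepError(f"subjects missing a recall day: {list(incomplete[:10])}")
    mean = (dense.groupby(["subject_id", "food_group"], sort=False)["amount"]
            .mean().reset_index())
    mean.insert(1, "day", 1)
    return mean[INTAKE_COLUMNS]


def categorize_intake(
    intake: pd.DataFrame, median_map: dict[str, float] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Code intake into three ordinal categories per food group.

    For each food group the cutoff is the median amount among *consumers*
    (records with amount > 0, pooling the recall days), unless a
    previously computed ``median_map`` is supplied for reuse on new data.
    Coding: 0 = nil, 1 = positive and at or below the median (ties code
    low), 2 = above the median.
    """
    dense = densify(intake)
    if median_map is None:
        consumers = dense[dense["amount"] > 0]
        no_consumers = set(dense["food_group"]) - set(consumers["food_group"])
        if no_consumers:
            raise DataPrepError(
                f"food groups with no positive amounts (should have been filtered): "
                f"{sorted(no_consumers)}")
        median_map = consumers.groupby("food_group")["amount"].median().to_dict()
    missing = set(dense["food_group"]) - set(median_map)
    if missing:
        raise DataPrepError(f"median map missing food groups: {sorted(missing)}")

    med = dense["food_group"].map(median_map)
    category = np.where(dense["amount"] == 0, NIL,
                        np.where(dense["amount"] <= med, BELOW_MEDIAN, ABOVE_MEDIAN))
    ordinal = dense[["subject_id", "day", "food_group"]].copy()
    ordinal.columns = ["subject_id", "day", "item"]
    ordinal["category"] = category.astype(int)
    return ordinal, dict(median_map)


def compute_icc(intake: pd.DataFrame) -> pd.Series:
    """One-way random-effects ICC per food group from the two recall days.

    ICC = (MS_between - MS_within) / (MS_between + MS_within) with two
    measurements per subject, floored at 0. A group with zero total
    variance has no defined ICC and is reported as NaN with a warning.
    Low values indicate large day-to-day (within-person) variability.
    """
    dense = densify(intake)
    days = sorted(dense["day"].unique())
    if len(days) != 2:
        raise DataPrepError("ICC requires exactly two recall days")
    out = {}
    for group, sub in dense.groupby("food_group"):
        wide = sub.pivot(index="subject_id", columns="day", values="amount").to_numpy()
        n = wide.shape[0]
        subj_mean = wide.mean(axis=1)
        grand = wide.mean()
        ms_between = 2.0 * np.sum((subj_mean - grand) ** 2) / (n - 1)
        ms_within = np.sum((wide - subj_mean[:, None]) ** 2) / n
        total = ms_between + ms_within
        if total == 0:
            warnings.warn(f"zero total variance for {group!r}; ICC undefined",
                          stacklevel=2)
            out[group] = np.nan
        else:
            out[group] = max(0.0, (ms_between - ms_within) / total)
    return pd.Series(out, name="icc").rename_axis("food_group")
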