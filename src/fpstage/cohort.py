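"""Cohort summaries and one-way ANOVA with eta-squared effect size.

Groups are the House-Brackmann grades; the response is one staged feature
(a shift difference in mm or an asymmetry index).  The fixed-effects
decomposition is

    F  = (SS_between / (k - 1)) / (SS_within / (N - k))
    R2 = SS_between / SS_total          (eta-squared)

R2 is the proportion of total variance explained by grade membership, the
"R-squared" that common ANOVA software prints; no adjusted variant is
used.  Display rounding is half-away-from-zero to 2 decimals, matching the
source tables' convention; raw values are always retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .asymmetry import (
    CALIBRATED_GRADES,
    FeatureID,
    Grade,
    GradeRangeTable,
    packaged_ranges,
)

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "CohortReport",
    "group_summary",
    "one_way_anova",
    "reproduce_tables",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Decimal-based so that e.g. 3.375 -> 3.38 (binary ``round`` would give
    3.37 or 3.38 depending on representation).  NaN passes through.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return math.nan
    q = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, max, min and sample standard deviation of one group."""

    n: int
    mean: float
    maximum: float
    minimum: float
    sd: float  # n-1 denominator; NaN for n < 2


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Summarise one group of feature values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty group")
    if not np.isfinite(v).all():
        raise ValueError("group values must be finite")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else math.nan
    return GroupSummary(
        n=int(v.size),
        mean=float(np.mean(v)),
        maximum=float(np.max(v)),
        minimum=float(np.min(v)),
        sd=sd,
    )


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA outcome."""

    F: float
    r_squared: float
    df_between: int
    df_within: int
    group_means: tuple[float, ...]
    note: str = ""


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA over k groups with the standard SS decomposition.

    Degenerate inputs follow fixed conventions rather than erroring: zero
    within-group variance with unequal means reports ``F = inf``; all
    values identical reports ``F = 0`` (both noted in ``note``).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    if any(not np.isfinite(a).all() for a in arrays):
        raise ValueError("group values must be finite")

    k = len(arrays)
    total = np.concatenate(arrays)
    n_total = total.size
    grand = total.mean()
    means = tuple(float(a.mean()) for a in arrays)
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    ss_total = ss_between + ss_within
    df_b, df_w = k - 1, n_total - k

    note = ""
    if ss_total == 0.0:
        f_stat, r2, note = 0.0, 0.0, "all values identical; F = 0 by convention"
    elif ss_within == 0.0:
        f_stat, r2 = math.inf, 1.0
        note = "zero within-group variance with unequal means; F = +inf"
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        r2 = ss_between / ss_total
    return AnovaResult(
        F=f_stat,
        r_squared=r2,
        df_between=df_b,
        df_within=df_w,
        group_means=means,
        note=note,
    )


@dataclass(frozen=True)
class CohortReport:
    """Per-feature, per-grade summaries plus the per-feature ANOVA."""

    summaries: dict[FeatureID, dict[Grade, GroupSummary]]
    anova: dict[FeatureID, AnovaResult]
    out_of_range: list[dict] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Summaries as a tidy DataFrame (display-rounded columns included)."""
        rows = []
        for fid, per_grade in self.summaries.items():
            for grade, s in per_grade.items():
                rows.append(
                    {
                        "feature": fid.value,
                        "grade": grade.value,
                        "n": s.n,
                        "mean": s.mean,
                        "max": s.maximum,
                        "min": s.minimum,
                        "sd": s.sd,
                        "mean_2dp": round_half_away(s.mean),
                        "max_2dp": round_half_away(s.maximum),
                        "min_2dp": round_half_away(s.minimum),
                        "sd_2dp": round_half_away(s.sd),
                    }
                )
        return pd.DataFrame(rows)

    def anova_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": fid.value,
                "F": a.F,
                "r_squared": a.r_squared,
                "df_between": a.df_between,
                "df_within": a.df_within,
                "note": a.note,
            }
            for fid, a in self.anova.items()
        ]
        return pd.DataFrame(rows)


def reproduce_tables(
    cohort: pd.DataFrame,
    table: Optional[GradeRangeTable] = None,
) -> CohortReport:
    """Build the per-grade summary tables and ANOVAs from a labelled cohort.

    ``cohort`` is tidy with columns ``subject, grade, feature, value``
    (grades in II..V, features in :class:`FeatureID`).  Every value is also
    checked against its grade's calibrated interval; outliers are recorded
    in ``out_of_range``, not rejected.  Grades with fewer than 2 members
    are excluded from the ANOVA with a warning.
    """
    required = {"subject", "grade", "feature", "value"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort frame needs columns {sorted(required)}")
    if table is None:
        table = packaged_ranges()

    summaries: dict[FeatureID, dict[Grade, GroupSummary]] = {}
    anova: dict[FeatureID, AnovaResult] = {}
    out_of_range: list[dict] = []

    for feature_label, feat_df in cohort.groupby("feature", sort=False):
        fid = FeatureID(feature_label)
        per_grade: dict[Grade, GroupSummary] = {}
        groups: list[np.ndarray] = []
        for grade in CALIBRATED_GRADES:
            sub = feat_df[feat_df["grade"] == grade.value]
            if sub.empty:
                continue
            vals = sub["value"].to_numpy(dtype=float)
            per_grade[grade] = group_summary(vals)
            if vals.size >= 2:
                groups.append(vals)
            else:
                warnings.warn(
                    f"{fid.value}: grade {grade.value} has {vals.size} member(s); "
                    "excluded from ANOVA",
                    stacklevel=2,
                )
            lo, hi = table.interval(fid, grade)
            for _, row in sub.iterrows():
                if not lo <= row["value"] <= hi:
                    out_of_range.append(
                        {
                            "feature": fid.value,
                            "grade": grade.value,
                            "subject": row["subject"],
                            "value": float(row["value"]),
                            "interval": [lo, hi],
                        }
                    )
        summaries[fid] = per_grade
        if len(groups) >= 2:
            anova[fid] = one_way_anova(groups)
    return CohortReport(summaries=summaries, anova=anova, out_of_range=out_of_range)
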