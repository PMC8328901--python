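"""Access to the packaged 40-patient calibration cohort.

The cohort (10 subjects per House-Brackmann grade II-V) is the data the
grade ranges were calibrated on: per-patient shift differences for the two
movements, their totals, and the two partial asymmetry indices, together
with the summary rows (Mean/Max/Min/St.dev.) as originally printed.

A few printed summary cells disagree with their own per-patient columns by
one unit in the last digit (typesetting/rounding slips in the source);
:func:`audit_printed_summaries` recomputes every cell and reports the
mismatches, and the test suite pins the audited set.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

from .asymmetry import FeatureID, Grade
from .cohort import group_summary, round_half_away

__all__ = [
    "reference_cohort",
    "reference_values",
    "reference_cohort_frame",
    "printed_summaries",
    "published_anova",
    "printed_cell_tolerance",
    "audit_printed_summaries",
]

GRADES = (Grade.II, Grade.III, Grade.IV, Grade.V)

#: The five feature columns printed per patient (TOTAL_AI is derived).
PRINTED_FEATURES = (
    FeatureID.FOREHEAD_SD,
    FeatureID.MOUTH_SD,
    FeatureID.TOTAL_SD,
    FeatureID.FOREHEAD_AI,
    FeatureID.MOUTH_AI,
)


@lru_cache(maxsize=1)
def reference_cohort() -> dict:
    """The raw packaged cohort record."""
    text = resources.files("fpstage").joinpath("data/reference_cohort.json").read_text()
    return json.loads(text)


def reference_values(feature: FeatureID, grade: Grade) -> list[float]:
    """The ten printed per-patient values of one feature column."""
    if feature is FeatureID.TOTAL_AI:
        a = reference_cohort()["values"]["FOREHEAD_AI"][grade.value]
        b = reference_cohort()["values"]["MOUTH_AI"][grade.value]
        return [(x + y) / 2.0 for x, y in zip(a, b)]
    return list(reference_cohort()["values"][feature.value][grade.value])


def reference_cohort_frame() -> pd.DataFrame:
    """Tidy cohort table with columns subject, grade, feature, value.

    Includes the derived TOTAL_AI feature (mean of the two partial indices)
    alongside the five printed features.
    """
    rows = []
    for grade in GRADES:
        for i in range(reference_cohort()["n_per_grade"]):
            subject = f"HB{grade.value}-{i + 1:02d}"
            for fid in FeatureID:
                rows.append(
                    {
                        "subject": subject,
                        "grade": grade.value,
                        "feature": fid.value,
                        "value": reference_values(fid, grade)[i],
                    }
                )
    return pd.DataFrame(rows)


def printed_summaries() -> dict:
    """The Mean/Max/Min/St.dev. rows exactly as printed in the source tables."""
    return reference_cohort()["printed_summaries"]


def published_anova() -> dict:
    """The published one-way ANOVA F and R-squared per feature."""
    return reference_cohort()["published_anova"]


def printed_cell_tolerance(feature: FeatureID, grade: Grade, index: int) -> float:
    """Half-ulp of one printed per-patient cell (0.005 for the usual 2
    decimals; coarser for the few cells printed to 1 decimal)."""
    key = f"{feature.value}.{grade.value}.{index}"
    decimals = reference_cohort()["printed_decimals_exceptions"].get(key, 2)
    return 0.5 * 10.0 ** (-decimals)


def audit_printed_summaries() -> dict[tuple[str, str, str], tuple[float, float]]:
    """Recompute every printed summary cell from its per-patient column.

    Returns the mismatching cells as
    ``{(feature, grade, stat): (printed, recomputed)}`` where *recomputed*
    is the exact column statistic rounded half-away-from-zero to 2
    decimals.  Matching cells are omitted.
    """
    mismatches = {}
    for fid in PRINTED_FEATURES:
        for grade in GRADES:
            col = reference_values(fid, grade)
            summary = group_summary(col)
            computed = {
                "mean": round_half_away(summary.mean),
                "max": round_half_away(summary.maximum),
                "min": round_half_away(summary.minimum),
                "sd": round_half_away(summary.sd),
            }
            for stat, value in computed.items():
                printed = printed_summaries()[fid.value][stat][grade.value]
                if abs(value - printed) > 1e-12:
                    mismatches[(fid.value, grade.value, stat)] = (printed, value)
    return mismatches
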