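"""Bilateral asymmetry quantities and House-Brackmann staging.

From the four per-side shifts (forehead and mouth, healthy and affected
side) this module derives the quantities the staging system is built on:

* **shift difference (SD)** — healthy-side shift minus affected-side shift
  for one movement (mm); grows with palsy severity;
* **asymmetry index (AI)** — affected-side shift divided by healthy-side
  shift (dimensionless); near 1 in normal faces (normals range up to about
  1.2), falling towards 0 with severity;
* **totals** — the two shift differences summed, and the two asymmetry
  indices averaged, so the total AI stays on the same 0-1.2 scale as the
  partial indices.

Each of the six derived features (partial and total SD and AI) carries a
calibrated per-grade interval for House-Brackmann grades II-V, packaged
from the Min/Max rows of the published 40-patient calibration cohort.
Grades I (normal) and VI (total paralysis) are outside the calibrated
ranges and are reported only as "better-than-II" or out-of-range beyond V,
never silently extrapolated.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

from .kinematics import Expression, ShiftMeasure
from .landmarks import Feature, Side

__all__ = [
    "FLAG_NO_SCALE",
    "FLAG_NEGATIVE_SHIFT",
    "FLAG_UNSTABLE_RATIO",
    "Grade",
    "FeatureID",
    "MovementAsymmetry",
    "AsymmetryResult",
    "GradeRangeTable",
    "FeatureGrade",
    "GradeAssignment",
    "shift_difference",
    "asymmetry_index",
    "assemble_result",
    "assign_grade",
    "grade_patient",
    "packaged_ranges",
]

FLAG_NO_SCALE = "no-scale"
FLAG_NEGATIVE_SHIFT = "negative-shift"
FLAG_UNSTABLE_RATIO = "unstable-ratio"

#: Healthy-side shifts at or below this are too small to divide by (mm/px).
AI_EPSILON = 1e-6


class Grade(str, enum.Enum):
    """Assignable staging outcomes, mildest first."""

    BETTER_THAN_II = "better-than-II"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"


#: Severity rank used for conservative tie-breaking.
_SEVERITY = {g: i for i, g in enumerate(Grade)}

#: The calibrated grades, mildest first.
CALIBRATED_GRADES = (Grade.II, Grade.III, Grade.IV, Grade.V)


class FeatureID(str, enum.Enum):
    """The six staged features: partial/total shift difference and asymmetry index."""

    FOREHEAD_SD = "FOREHEAD_SD"
    MOUTH_SD = "MOUTH_SD"
    TOTAL_SD = "TOTAL_SD"
    FOREHEAD_AI = "FOREHEAD_AI"
    MOUTH_AI = "MOUTH_AI"
    TOTAL_AI = "TOTAL_AI"

    @property
    def kind(self) -> str:
        """``"sd"`` (higher = more severe) or ``"ai"`` (lower = more severe)."""
        return "sd" if self.value.endswith("_SD") else "ai"


def shift_difference(healthy_shift: float, affected_shift: float) -> float:
    """Healthy-side shift minus affected-side shift, sign preserved."""
    return healthy_shift - affected_shift


def asymmetry_index(
    affected_shift: float, healthy_shift: float, eps: float = AI_EPSILON
) -> tuple[float, frozenset[str]]:
    """Affected/healthy shift ratio with stability flags, never an exception.

    Returns ``(value, flags)``.  A negative affected shift is clamped to 0
    before the ratio (flagged ``negative-shift``); a healthy shift at or
    below ``eps`` makes the ratio undefined, returned as NaN with the
    ``unstable-ratio`` flag.
    """
    flags: set[str] = set()
    num = affected_shift
    if num < 0:
        num = 0.0
        flags.add(FLAG_NEGATIVE_SHIFT)
    if not healthy_shift > eps:
        flags.add(FLAG_UNSTABLE_RATIO)
        return math.nan, frozenset(flags)
    return num / healthy_shift, frozenset(flags)


@dataclass(frozen=True)
class MovementAsymmetry:
    """Per-movement healthy/affected shifts and derived quantities."""

    expression: Expression
    feature: Feature
    healthy_shift: float
    affected_shift: float
    shift_difference: float
    asymmetry_index: float  # NaN when undefined


@dataclass(frozen=True)
class AsymmetryResult:
    """The staging quantities of one subject (both movements plus totals)."""

    frown: MovementAsymmetry
    smile: MovementAsymmetry
    total_shift_difference: float
    total_asymmetry_index: float
    unit: str = "mm"
    flags: frozenset[str] = frozenset()

    def feature_value(self, feature_id: FeatureID) -> float:
        """The value graded under a given feature id."""
        return {
            FeatureID.FOREHEAD_SD: self.frown.shift_difference,
            FeatureID.MOUTH_SD: self.smile.shift_difference,
            FeatureID.TOTAL_SD: self.total_shift_difference,
            FeatureID.FOREHEAD_AI: self.frown.asymmetry_index,
            FeatureID.MOUTH_AI: self.smile.asymmetry_index,
            FeatureID.TOTAL_AI: self.total_asymmetry_index,
        }[feature_id]


_EXPR_FEATURE = {Expression.FROWN: Feature.FOREHEAD, Expression.SMILE: Feature.MOUTH}


def assemble_result(
    shifts: Mapping[tuple[Expression, Side], ShiftMeasure],
    affected_side: Optional[Side],
    total_ai_mode: str = "mean",
) -> AsymmetryResult:
    """Resolve healthy/affected roles and build the full asymmetry result.

    ``affected_side`` must be a concrete side: a face without an
    affected-side label cannot be staged.  ``total_ai_mode`` selects how the
    two partial indices aggregate (``"mean"`` keeps the total on the partial
    0-1.2 scale; ``"sum"`` is available for comparison).
    """
    if affected_side is None:
        raise ValueError("cannot stage a face without an affected-side label")
    if total_ai_mode not in ("mean", "sum"):
        raise ValueError(f"total_ai_mode must be 'mean' or 'sum', got {total_ai_mode!r}")

    flags: set[str] = set()
    units = {m.unit for m in shifts.values()}
    if len(units) != 1:
        raise ValueError(f"mixed shift units {units}")
    unit = units.pop()
    if unit == "px":
        flags.add(FLAG_NO_SCALE)

    movements: dict[Expression, MovementAsymmetry] = {}
    for expr in Expression:
        try:
            healthy = shifts[(expr, affected_side.other)].shift
            affected = shifts[(expr, affected_side)].shift
        except KeyError as exc:
            raise ValueError(f"missing shift measure for {expr.value}") from exc
        sd = shift_difference(healthy, affected)
        ai, ai_flags = asymmetry_index(affected, healthy)
        flags |= ai_flags
        if healthy < 0 or affected < 0 or sd < 0:
            flags.add(FLAG_NEGATIVE_SHIFT)
        movements[expr] = MovementAsymmetry(
            expression=expr,
            feature=_EXPR_FEATURE[expr],
            healthy_shift=healthy,
            affected_shift=affected,
            shift_difference=sd,
            asymmetry_index=ai,
        )

    frown, smile = movements[Expression.FROWN], movements[Expression.SMILE]
    total_sd = frown.shift_difference + smile.shift_difference
    ais = (frown.asymmetry_index, smile.asymmetry_index)
    if any(math.isnan(a) for a in ais):
        total_ai = math.nan
    elif total_ai_mode == "mean":
        total_ai = (ais[0] + ais[1]) / 2.0
    else:
        total_ai = ais[0] + ais[1]

    return AsymmetryResult(
        frown=frown,
        smile=smile,
        total_shift_difference=total_sd,
        total_asymmetry_index=total_ai,
        unit=unit,
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# Grade range table


@dataclass(frozen=True)
class GradeRangeTable:
    """Per-feature, per-grade closed value intervals calibrating the stages.

    ``ranges[feature][grade] = (lo, hi)``.  Interval systems must be
    monotone and non-overlapping: SD intervals increase with grade, AI
    intervals decrease — asserted at construction.
    """

    ranges: Mapping[FeatureID, Mapping[Grade, tuple[float, float]]]
    notes: Mapping[str, str] = field(default_factory=dict)
    schema_version: int = 1

    def __post_init__(self) -> None:
        for fid, grades in self.ranges.items():
            missing = [g for g in CALIBRATED_GRADES if g not in grades]
            if missing:
                raise ValueError(f"{fid.value}: missing grades {[g.value for g in missing]}")
            for g, (lo, hi) in grades.items():
                if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                    raise ValueError(f"{fid.value} {g.value}: invalid interval [{lo}, {hi}]")
            ordered = [grades[g] for g in CALIBRATED_GRADES]
            if fid.kind == "sd":
                ok = all(a[1] < b[0] for a, b in zip(ordered, ordered[1:]))
            else:
                ok = all(b[1] < a[0] for a, b in zip(ordered, ordered[1:]))
            if not ok:
                raise ValueError(
                    f"{fid.value}: intervals must be {'increasing' if fid.kind == 'sd' else 'decreasing'} "
                    f"with grade and non-overlapping"
                )

    def interval(self, feature_id: FeatureID, grade: Grade) -> tuple[float, float]:
        return self.ranges[feature_id][grade]

    def to_json_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "notes": dict(self.notes),
            "features": {
                fid.value: {
                    "kind": fid.kind,
                    "grades": {g.value: [lo, hi] for g, (lo, hi) in grades.items()},
                }
                for fid, grades in self.ranges.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GradeRangeTable":
        ranges = {
            FeatureID(fid): {
                Grade(g): (float(lo), float(hi))
                for g, (lo, hi) in entry["grades"].items()
            }
            for fid, entry in d["features"].items()
        }
        return cls(
            ranges=ranges,
            notes=d.get("notes", {}),
            schema_version=int(d.get("schema_version", 1)),
        )


@lru_cache(maxsize=1)
def packaged_ranges() -> GradeRangeTable:
    """The grade-range table shipped with the package."""
    text = resources.files("fpstage").joinpath("data/grade_ranges.json").read_text()
    return GradeRangeTable.from_json_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Grade assignment


@dataclass(frozen=True)
class FeatureGrade:
    """Outcome of staging a single feature value."""

    grade: Optional[Grade]
    status: str  # in-range | nearest-range | out-of-range | unclassifiable
    note: str = ""


@dataclass(frozen=True)
class GradeAssignment:
    """Per-feature grades, the combined grade, and a human-readable rationale."""

    feature_grades: Mapping[FeatureID, FeatureGrade]
    combined: Optional[Grade]
    primary_feature: FeatureID
    rationale: str


def assign_grade(
    value: float,
    feature_id: FeatureID,
    table: Optional[GradeRangeTable] = None,
    gap_mode: str = "nearest",
) -> FeatureGrade:
    """Stage one feature value against its calibrated intervals.

    Values inside an interval map to that grade.  Values in a gap between
    adjacent intervals map to the grade with the nearest interval boundary,
    ties going to the more severe grade (clinically conservative); with
    ``gap_mode="refuse"`` gap values are returned unclassifiable instead.
    Values milder than the grade-II interval are "better-than-II"; values
    beyond the grade-V interval are V, both with out-of-range status.
    """
    if table is None:
        table = packaged_ranges()
    if gap_mode not in ("nearest", "refuse"):
        raise ValueError(f"gap_mode must be 'nearest' or 'refuse', got {gap_mode!r}")
    if math.isnan(value):
        return FeatureGrade(None, "unclassifiable", "value undefined (NaN)")

    grades = table.ranges[feature_id]
    for g in CALIBRATED_GRADES:
        lo, hi = grades[g]
        if lo <= value <= hi:
            return FeatureGrade(g, "in-range")

    # Order intervals mildest-to-most-severe along the value axis.
    sd = feature_id.kind == "sd"
    mild_end, severe_end = (Grade.II, Grade.V)
    lo2, hi2 = grades[mild_end]
    lo5, hi5 = grades[severe_end]
    if (sd and value < lo2) or (not sd and value > hi2):
        return FeatureGrade(
            Grade.BETTER_THAN_II, "out-of-range", "milder than the grade-II interval"
        )
    if (sd and value > hi5) or (not sd and value < lo5):
        return FeatureGrade(Grade.V, "out-of-range", "beyond the grade-V interval")

    # In a gap between two adjacent calibrated intervals.
    for g_mild, g_severe in zip(CALIBRATED_GRADES, CALIBRATED_GRADES[1:]):
        if sd:
            gap = (grades[g_mild][1], grades[g_severe][0])
            inside = gap[0] < value < gap[1]
            d_mild, d_severe = value - gap[0], gap[1] - value
        else:
            gap = (grades[g_severe][1], grades[g_mild][0])
            inside = gap[0] < value < gap[1]
            d_mild, d_severe = gap[1] - value, value - gap[0]
        if inside:
            if gap_mode == "refuse":
                return FeatureGrade(
                    None,
                    "unclassifiable",
                    f"in the gap between grades {g_mild.value} and {g_severe.value}",
                )
            g = g_severe if d_severe <= d_mild else g_mild
            return FeatureGrade(
                g,
                "nearest-range",
                f"in the {g_mild.value}/{g_severe.value} gap, nearest to {g.value} "
                f"(distance {min(d_mild, d_severe):.3g} vs {max(d_mild, d_severe):.3g})",
            )
    raise AssertionError(f"unreachable: {feature_id.value} value {value}")  # pragma: no cover


def grade_patient(
    result: AsymmetryResult,
    table: Optional[GradeRangeTable] = None,
    gap_mode: str = "nearest",
) -> GradeAssignment:
    """Stage a subject from all six features and combine into one grade.

    The combined grade follows the total shift difference when measurements
    are calibrated (mm); without a scale, shift differences are in pixels
    and not comparable to the calibrated mm intervals, so the combined
    grade follows the scale-free total asymmetry index instead.  The
    rationale lists every per-feature grade and any disagreement with the
    combined grade.
    """
    if table is None:
        table = packaged_ranges()
    feature_grades = {
        fid: assign_grade(result.feature_value(fid), fid, table, gap_mode)
        for fid in FeatureID
    }
    primary = FeatureID.TOTAL_SD if result.unit == "mm" else FeatureID.TOTAL_AI
    combined = feature_grades[primary].grade

    lines = [
        f"combined grade {combined.value if combined else 'unclassifiable'} "
        f"from {primary.value}"
    ]
    disagree = []
    for fid, fg in feature_grades.items():
        val = result.feature_value(fid)
        lines.append(
            f"  {fid.value}: {val:.3f} -> "
            f"{fg.grade.value if fg.grade else 'unclassifiable'} ({fg.status})"
        )
        if fg.grade is not None and combined is not None and fg.grade is not combined:
            disagree.append(fid.value)
    if disagree:
        lines.append(f"  disagreement with combined grade: {', '.join(disagree)}")
    return GradeAssignment(
        feature_grades=feature_grades,
        combined=combined,
        primary_feature=primary,
        rationale="\n".join(lines),
    )
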