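"""From landmark tracks to per-side feature time series and movement shifts.

The pipeline stage implemented here turns a :class:`~fpstage.landmarks.LandmarkTrack`
into four distance-versus-time signals (forehead and mouth feature, each on
both hemifaces), locates the rest baseline and the two movement windows
(forehead frowning, then smiling, in protocol order), and computes the
*shift* of each side during each movement:

    shift = max(distance over the movement window) - mean(distance at rest)

The shift is the side's real excursion: subtracting the resting distance
removes the anatomical baseline so that only movement remains.  A flaccid
side can legitimately produce a shift of (or near) zero.

Frame intervals are half-open ``[a, b)`` over 0-based frame indices,
everywhere (files, annotations, return values).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .landmarks import (
    DEFAULT_POINT_MAP,
    Feature,
    LandmarkTrack,
    Side,
    SidePointMap,
    feature_distance,
)

__all__ = [
    "Expression",
    "EXPRESSION_FEATURE",
    "FeatureSeries",
    "SeriesBundle",
    "MovementWindows",
    "ShiftMeasure",
    "extract_series",
    "detect_windows",
    "rest_mean",
    "max_excursion",
    "shift",
    "measure_shifts",
    "WindowDetectionError",
]


class Expression(str, enum.Enum):
    """The two analysed voluntary expressions, in protocol order."""

    FROWN = "FROWN"
    SMILE = "SMILE"


#: Which feature each expression acts on.
EXPRESSION_FEATURE: dict[Expression, Feature] = {
    Expression.FROWN: Feature.FOREHEAD,
    Expression.SMILE: Feature.MOUTH,
}


class WindowDetectionError(ValueError):
    """Raised when rest/movement windows cannot be located or are invalid."""


@dataclass(frozen=True)
class FeatureSeries:
    """One feature's distance signal on one hemiface, aligned to frames."""

    feature: Feature
    side: Side
    values: np.ndarray  # one distance per frame
    unit: str = "mm"  # "mm" when calibrated, "px" otherwise

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("series values must be a non-empty 1-D array")
        if not np.isfinite(v).all():
            raise ValueError("series values must be finite")
        if (v < 0).any():
            raise ValueError("feature distances cannot be negative")
        if self.unit not in ("mm", "px"):
            raise ValueError(f"unit must be 'mm' or 'px', got {self.unit!r}")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SeriesBundle:
    """The four per-side feature series of one track, plus track context."""

    series: Mapping[tuple[Feature, Side], FeatureSeries]
    frames_per_second: float
    affected_side: Optional[Side] = None

    def __post_init__(self) -> None:
        keys = {(f, s) for f in Feature for s in Side}
        if set(self.series.keys()) != keys:
            raise ValueError("bundle must hold exactly the four feature/side series")
        lengths = {len(s) for s in self.series.values()}
        if len(lengths) != 1:
            raise ValueError("all series in a bundle must have equal length")

    def __getitem__(self, key: tuple[Feature, Side]) -> FeatureSeries:
        return self.series[key]

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.series.values())))

    @property
    def healthy_side(self) -> Optional[Side]:
        return None if self.affected_side is None else self.affected_side.other


Interval = tuple[int, int]  # half-open [a, b) in frame indices


def _check_interval(iv: Interval, n: int, what: str) -> Interval:
    a, b = int(iv[0]), int(iv[1])
    if not (0 <= a < b <= n):
        raise WindowDetectionError(
            f"{what} interval [{a}, {b}) is empty or outside track bounds [0, {n})"
        )
    return (a, b)


@dataclass(frozen=True)
class MovementWindows:
    """Rest intervals and one movement interval per analysed expression."""

    rest: tuple[Interval, ...]
    movement: Mapping[Expression, Interval]

    def validate(self, n_frames: int) -> "MovementWindows":
        """Bounds- and disjointness-check against a track length; returns self."""
        if not self.rest:
            raise WindowDetectionError("at least one rest interval is required")
        for iv in self.rest:
            _check_interval(iv, n_frames, "rest")
        for expr, iv in self.movement.items():
            _check_interval(iv, n_frames, f"{expr.value} movement")
            for r in self.rest:
                if iv[0] < r[1] and r[0] < iv[1]:
                    raise WindowDetectionError(
                        f"{expr.value} movement interval {iv} overlaps rest interval {r}"
                    )
        ivs = sorted(self.movement.values())
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise WindowDetectionError("movement intervals overlap")
        return self

    def to_json_dict(self) -> dict:
        return {
            "rest": [list(iv) for iv in self.rest],
            "movement": {e.value: list(iv) for e, iv in self.movement.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MovementWindows":
        return cls(
            rest=tuple((int(a), int(b)) for a, b in d["rest"]),
            movement={Expression(k): (int(a), int(b)) for k, (a, b) in d["movement"].items()},
        )

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2)


@dataclass(frozen=True)
class ShiftMeasure:
    """One side's shift for one movement, with its two components."""

    feature: Feature
    side: Side
    rest_mean: float
    max_excursion: float
    unit: str = "mm"

    @property
    def shift(self) -> float:
        return self.max_excursion - self.rest_mean


def extract_series(
    track: LandmarkTrack,
    point_map: SidePointMap = DEFAULT_POINT_MAP,
    scale=None,
    projected: bool = True,
) -> SeriesBundle:
    """Compute the four feature series of a track.

    Vectorised over frames; each value equals
    :func:`fpstage.landmarks.feature_distance` on that frame.
    """
    coords = track.coords()  # (n, 68, 2)
    t = 1.0 if scale is None else scale.t
    unit = "px" if scale is None else "mm"
    series: dict[tuple[Feature, Side], FeatureSeries] = {}
    for side in Side:
        pts = point_map.for_side(side)
        brow = coords[:, pts.eyebrow - 1]
        lid = coords[:, pts.upper_lid - 1]
        corner = coords[:, pts.mouth_corner - 1]
        center = coords[:, point_map.mouth_center - 1]
        if projected:
            forehead = np.abs(brow[:, 1] - lid[:, 1])
            mouth = np.abs(corner[:, 0] - center[:, 0])
        else:
            forehead = np.hypot(*(brow - lid).T)
            mouth = np.hypot(*(corner - center).T)
        series[(Feature.FOREHEAD, side)] = FeatureSeries(
            Feature.FOREHEAD, side, forehead * t, unit
        )
        series[(Feature.MOUTH, side)] = FeatureSeries(Feature.MOUTH, side, mouth * t, unit)
    return SeriesBundle(
        series=series,
        frames_per_second=track.frames_per_second,
        affected_side=track.affected_side,
    )


def _detection_signal(bundle: SeriesBundle, feature: Feature) -> np.ndarray:
    """Series used to centre a movement window: the healthy side if known,
    else the frame-wise mean of both sides."""
    if bundle.healthy_side is not None:
        return bundle[(feature, bundle.healthy_side)].values
    a = bundle[(feature, Side.A)].values
    b = bundle[(feature, Side.B)].values
    return (a + b) / 2.0


def detect_windows(
    bundle: SeriesBundle,
    annotations: Optional[MovementWindows] = None,
    k_mad: float = 3.0,
    min_rest_s: float = 0.5,
    window_s: float = 1.0,
    sustain_frames: int = 5,
) -> MovementWindows:
    """Locate rest and movement windows, or validate supplied annotations.

    Explicit annotations always win: they are bounds-checked and returned
    verbatim.  Otherwise the windows are auto-detected:

    * **rest** — the maximal initial interval over which every series stays
      within ``k_mad`` median absolute deviations of its initial-second
      median.  The interval ends at the first *sustained, sign-consistent*
      exceedance (``sustain_frames`` consecutive frames deviating beyond
      the band in the same direction in the same series); isolated jitter
      excursions, which have random signs, are ignored.  A rest baseline
      shorter than ``min_rest_s`` is an error.
    * **FROWN** — a window of width ``window_s`` centred on the post-rest
      global maximum of the forehead series (healthy side when known).
    * **SMILE** — likewise on the mouth series, searched after the frown
      window, enforcing the protocol order frown-then-smile.
    """
    n = bundle.n_frames
    if annotations is not None:
        return annotations.validate(n)

    fps = bundle.frames_per_second
    init = max(2, min(n, int(round(fps))))  # the initial second
    min_rest = max(1, int(round(min_rest_s * fps)))

    # Movement onset: the first sustained one-directional departure of any
    # series from its initial-second median.
    rest_end = n
    for s in bundle.series.values():
        v = s.values
        med = float(np.median(v[:init]))
        mad = float(np.median(np.abs(v[:init] - med)))
        tol = k_mad * mad + 1e-12  # floor so an exactly-constant rest is in-band
        dev = v - med
        for sign in (1.0, -1.0):
            out = sign * dev > tol
            run = 0
            for i in range(min(n, rest_end + sustain_frames)):
                run = run + 1 if out[i] else 0
                if run >= sustain_frames:
                    rest_end = min(rest_end, i - sustain_frames + 1)
                    break
    if rest_end < min_rest:
        raise WindowDetectionError(
            f"no rest baseline: initial in-band interval is {rest_end} frames "
            f"({rest_end / fps:.2f} s), below the {min_rest_s} s minimum"
        )
    rest: tuple[Interval, ...] = ((0, rest_end),)

    half = max(1, int(round(window_s * fps / 2)))
    movement: dict[Expression, Interval] = {}
    search_start = rest_end
    for expr in (Expression.FROWN, Expression.SMILE):  # protocol order
        sig = _detection_signal(bundle, EXPRESSION_FEATURE[expr])
        if search_start >= n:
            raise WindowDetectionError(f"no frames left to search for {expr.value}")
        apex = search_start + int(np.argmax(sig[search_start:]))
        iv = (max(rest_end, apex - half), min(n, apex + half))
        movement[expr] = _check_interval(iv, n, f"{expr.value} movement")
        search_start = iv[1]

    return MovementWindows(rest=rest, movement=movement).validate(n)


def _rest_values(series: FeatureSeries, windows: MovementWindows) -> np.ndarray:
    parts = [series.values[a:b] for a, b in windows.rest]
    vals = np.concatenate(parts) if parts else np.empty(0)
    if vals.size == 0:
        raise WindowDetectionError("rest interval union is empty")
    return vals


def rest_mean(series: FeatureSeries, windows: MovementWindows) -> float:
    """Mean feature distance over the union of rest intervals."""
    return float(np.mean(_rest_values(series, windows)))


def max_excursion(
    series: FeatureSeries, windows: MovementWindows, expression: Expression
) -> float:
    """Maximum feature distance over the expression's movement window."""
    if expression not in windows.movement:
        raise WindowDetectionError(f"no movement window for {expression.value}")
    a, b = windows.movement[expression]
    return float(np.max(series.values[a:b]))


def shift(
    series: FeatureSeries, windows: MovementWindows, expression: Expression
) -> ShiftMeasure:
    """Shift of one side during one movement: max excursion minus rest mean.

    May be zero or negative for a side that does not move (or drifts below
    its resting distance); the caller decides how to flag that.
    """
    return ShiftMeasure(
        feature=series.feature,
        side=series.side,
        rest_mean=rest_mean(series, windows),
        max_excursion=max_excursion(series, windows, expression),
        unit=series.unit,
    )


def measure_shifts(
    bundle: SeriesBundle, windows: MovementWindows
) -> dict[tuple[Expression, Side], ShiftMeasure]:
    """Shift of both sides for both expressions: the staging inputs."""
    return {
        (expr, side): shift(bundle[(EXPRESSION_FEATURE[expr], side)], windows, expr)
        for expr in Expression
        for side in Side
        if expr in windows.movement
    }
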