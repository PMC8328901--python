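"""68-point facial landmark model and the geometric feature distances used for staging.

The staging pipeline measures two bilateral features on every video frame:

* ``FOREHEAD`` — the vertical gap between an eyebrow point and the upper
  eyelid rim of the same hemiface.  Forehead frowning (astonishment) raises
  the eyebrow and widens this gap.
* ``MOUTH`` — the horizontal gap between a mouth corner and the centre of
  the mouth.  Smiling pulls the corner laterally and widens this gap.

Landmarks follow the standard 68-point face-alignment numbering and are
addressed **1-based** everywhere in the public interface (point 1..68), the
convention used by the clinical point list: eyebrows 20/25, upper eyelid rims
38/45, lower eyelid rims 42/47, mouth corners 49/55, mouth centre 63.
Coordinates are planar pixels in image convention (x rightward, y downward).

The two hemifaces are labelled geometrically ``A`` and ``B``; which one is
"healthy" and which "affected" is metadata (:attr:`LandmarkTrack.affected_side`),
never inferred from the landmark data itself.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "N_LANDMARKS",
    "Feature",
    "Side",
    "LandmarkFrame",
    "SidePoints",
    "SidePointMap",
    "DEFAULT_POINT_MAP",
    "LandmarkTrack",
    "MalformedFrameError",
    "validate_frame",
    "feature_distance",
]

N_LANDMARKS = 68

#: Recording duration range (seconds) of the acquisition protocol; tracks
#: outside this range are accepted with a warning.
TYPICAL_DURATION_S = (15.0, 20.0)


class Feature(str, enum.Enum):
    """Bilateral kinematic feature measured on each frame."""

    FOREHEAD = "FOREHEAD"
    MOUTH = "MOUTH"


class Side(str, enum.Enum):
    """Geometric hemiface label (not a clinical left/right claim)."""

    A = "A"
    B = "B"

    @property
    def other(self) -> "Side":
        return Side.B if self is Side.A else Side.A


class MalformedFrameError(ValueError):
    """A frame that does not contain exactly 68 finite planar points."""


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame's 68 landmark coordinates.

    Parameters
    ----------
    frame_index : int
        0-based ordinal of the frame within its track.
    time_s : float
        Timestamp in seconds.
    points : numpy.ndarray, shape (68, 2)
        Pixel coordinates; row ``i`` holds point ``i + 1`` of the 1-based
        numbering (x rightward, y downward).
    """

    frame_index: int
    time_s: float
    points: np.ndarray

    def point(self, point_id: int) -> np.ndarray:
        """Return the (x, y) coordinates of a **1-based** point id."""
        if not 1 <= point_id <= N_LANDMARKS:
            raise ValueError(f"point id must be in 1..{N_LANDMARKS}, got {point_id}")
        return self.points[point_id - 1]


def validate_frame(
    raw_points: Sequence | np.ndarray,
    frame_index: int = 0,
    time_s: float = 0.0,
) -> LandmarkFrame:
    """Validate raw detector output into a :class:`LandmarkFrame`.

    Raises
    ------
    MalformedFrameError
        If the input does not hold exactly 68 points, a point is not planar,
        or any coordinate is non-finite (the error names the 1-based point id).
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise MalformedFrameError(
            f"malformed frame {frame_index}: expected an (n, 2) point array, "
            f"got shape {pts.shape}"
        )
    if pts.shape[0] != N_LANDMARKS:
        raise MalformedFrameError(
            f"malformed frame {frame_index}: expected {N_LANDMARKS} points, "
            f"got {pts.shape[0]}"
        )
    finite = np.isfinite(pts).all(axis=1)
    if not finite.all():
        bad = int(np.flatnonzero(~finite)[0]) + 1  # 1-based id
        raise MalformedFrameError(
            f"malformed frame {frame_index}: non-finite coordinate at point {bad}"
        )
    return LandmarkFrame(frame_index=frame_index, time_s=time_s, points=pts)


@dataclass(frozen=True)
class SidePoints:
    """The 1-based landmark ids of one hemiface's measured points."""

    eyebrow: int
    upper_lid: int
    lower_lid: int
    mouth_corner: int

    def ids(self) -> frozenset[int]:
        return frozenset((self.eyebrow, self.upper_lid, self.lower_lid, self.mouth_corner))


@dataclass(frozen=True)
class SidePointMap:
    """Mapping from hemiface label to the landmark ids used for measurement.

    Defaults follow the clinical point list: side A uses eyebrow 20, upper
    lid 38, lower lid 42, mouth corner 49; side B uses 25, 45, 47, 55; the
    shared mouth centre is point 63.  The lower-eyelid ids are carried for
    completeness of the model but take no part in staging (eye-closure
    movements are excluded from the analysis).
    """

    side_a: SidePoints = field(default_factory=lambda: SidePoints(20, 38, 42, 49))
    side_b: SidePoints = field(default_factory=lambda: SidePoints(25, 45, 47, 55))
    mouth_center: int = 63

    def __post_init__(self) -> None:
        all_ids = self.side_a.ids() | self.side_b.ids() | {self.mouth_center}
        for pid in all_ids:
            if not 1 <= pid <= N_LANDMARKS:
                raise ValueError(f"point id {pid} outside 1..{N_LANDMARKS}")
        if self.side_a.ids() & self.side_b.ids():
            raise ValueError("side A and side B point ids must be disjoint")
        if self.mouth_center in self.side_a.ids() | self.side_b.ids():
            raise ValueError("mouth centre id must not belong to either side")

    def for_side(self, side: Side) -> SidePoints:
        return self.side_a if side is Side.A else self.side_b


DEFAULT_POINT_MAP = SidePointMap()


@dataclass
class LandmarkTrack:
    """A timestamped sequence of landmark frames with subject metadata.

    ``affected_side`` is ``None`` for a face with no palsy label (e.g. a
    normal control); staging requires it to be set.
    """

    frames: list[LandmarkFrame]
    frames_per_second: float
    subject_id: str = ""
    affected_side: Optional[Side] = None
    hb_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a track needs at least one frame")
        if self.frames_per_second <= 0 or not np.isfinite(self.frames_per_second):
            raise ValueError("frames_per_second must be positive and finite")
        idx = np.array([f.frame_index for f in self.frames])
        if not (np.diff(idx) > 0).all():
            raise ValueError("frame_index must be strictly increasing")
        t = np.array([f.time_s for f in self.frames])
        if not (np.diff(t) >= 0).all():
            raise ValueError("time_s must be non-decreasing")
        lo, hi = TYPICAL_DURATION_S
        if len(self.frames) > 1 and not lo <= self.duration_s <= hi:
            warnings.warn(
                f"track duration {self.duration_s:.1f} s outside the typical "
                f"{lo:.0f}-{hi:.0f} s recording window",
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.frames[-1].time_s - self.frames[0].time_s

    def coords(self) -> np.ndarray:
        """All coordinates as an (n_frames, 68, 2) array."""
        return np.stack([f.points for f in self.frames])


def feature_distance(
    frame: LandmarkFrame,
    feature: Feature,
    side: Side,
    point_map: SidePointMap = DEFAULT_POINT_MAP,
    scale=None,
    projected: bool = True,
) -> float:
    """Measure one feature distance on one frame, in mm (or px without scale).

    With the default axis-projected geometry the forehead feature is the
    absolute **vertical** eyebrow-to-upper-lid gap and the mouth feature the
    absolute **horizontal** corner-to-centre gap, matching the planes in which
    the two expressions act (frowning moves the brow vertically, smiling the
    corner horizontally).  ``projected=False`` selects plain Euclidean
    distance instead.

    Parameters
    ----------
    scale : ScaleCalibration or None
        Pixel-to-mm calibration.  ``None`` leaves the result in pixels.
    """
    side_pts = point_map.for_side(side)
    if feature is Feature.FOREHEAD:
        p, q = frame.point(side_pts.eyebrow), frame.point(side_pts.upper_lid)
        axis = 1  # vertical plane
    else:
        p, q = frame.point(side_pts.mouth_corner), frame.point(point_map.mouth_center)
        axis = 0  # horizontal plane
    if projected:
        dist_px = abs(p[axis] - q[axis])
    else:
        dist_px = float(np.hypot(p[0] - q[0], p[1] - q[1]))
    t = 1.0 if scale is None else scale.t
    return float(dist_px * t)
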