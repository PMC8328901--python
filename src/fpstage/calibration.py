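"""Pixel-to-millimetre calibration.

All measurements start as pixel distances on the video frame and are
converted to millimetres by a single scale factor

    t = f[mm] / f[px]

where ``f`` is any feature of known physical size imaged at a known pixel
size.  Three sources are supported:

* ``marker`` — a circular adhesive marker of known diameter (5 mm in the
  original marker-based protocol) measured in pixels on the image;
* ``reference`` — any known physical length (e.g. an intercanthal distance
  measured with callipers) and its pixel extent;
* ``explicit`` — a user-supplied mm/px value.

Asymmetry indices are ratios of same-scale lengths and therefore do not
need a calibration at all; shift differences do, and are reported in px and
flagged as non-comparable to the calibrated grade ranges when no scale is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScaleCalibration",
    "scale_from_marker",
    "scale_from_reference",
    "explicit_scale",
    "DEFAULT_MARKER_MM",
]

#: Physical diameter of the adhesive markers of the predecessor protocol.
DEFAULT_MARKER_MM = 5.0


@dataclass(frozen=True)
class ScaleCalibration:
    """A positive, finite mm-per-pixel factor and where it came from."""

    t: float
    source: str = "explicit"

    def __post_init__(self) -> None:
        if not (isinstance(self.t, (int, float)) and math.isfinite(self.t) and self.t > 0):
            raise ValueError(f"scale t must be positive and finite, got {self.t!r}")
        if self.source not in ("marker", "reference", "explicit"):
            raise ValueError(f"unknown calibration source {self.source!r}")


def scale_from_marker(marker_px: float, marker_mm: float = DEFAULT_MARKER_MM) -> ScaleCalibration:
    """Calibrate from a physical marker of known size.

    ``t = marker_mm / marker_px``.
    """
    if not (math.isfinite(marker_px) and marker_px > 0):
        raise ValueError(f"marker size in px must be positive and finite, got {marker_px!r}")
    if not (math.isfinite(marker_mm) and marker_mm > 0):
        raise ValueError(f"marker size in mm must be positive and finite, got {marker_mm!r}")
    return ScaleCalibration(t=marker_mm / marker_px, source="marker")


def scale_from_reference(length_px: float, length_mm: float) -> ScaleCalibration:
    """Calibrate from any reference length of known physical size."""
    if not (math.isfinite(length_px) and length_px > 0):
        raise ValueError(f"reference length in px must be positive and finite, got {length_px!r}")
    if not (math.isfinite(length_mm) and length_mm > 0):
        raise ValueError(f"reference length in mm must be positive and finite, got {length_mm!r}")
    return ScaleCalibration(t=length_mm / length_px, source="reference")


def explicit_scale(t: float) -> ScaleCalibration:
    """Wrap a user-supplied mm/px factor."""
    return ScaleCalibration(t=t, source="explicit")
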