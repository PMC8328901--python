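"""File formats and the detector adapter contract.

Formats (all plain text, UTF-8):

* **trajectory CSV** — header ``frame,time_s,x1,y1,...,x68,y68``, one row
  per frame, ``#`` comment lines allowed; metadata (subject, fps, affected
  side, HB label) rides in leading ``# key=value`` comments.  Frames are
  0-based and strictly increasing.  Floats are written with ``repr`` so a
  write/read round-trip is bit-exact.
* **windows JSON** — half-open 0-based frame intervals per expression.
* **ranges JSON** — a grade-range table (see ``fpstage.data/grade_ranges.json``).
* **report JSON** — subject metadata, scale, windows used, the asymmetry
  result with flags, and the grade assignment with its rationale.

The video pathway is adapter-injected: :func:`detect_landmarks` consumes
any per-frame landmark backend (a callable mapping an image to 68 points
or ``None`` for no face) and never requires a pretrained model itself.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

import numpy as np

from . import __version__ as _version
from .asymmetry import (
    AsymmetryResult,
    GradeAssignment,
    GradeRangeTable,
    MovementAsymmetry,
)
from .calibration import ScaleCalibration
from .kinematics import Expression, MovementWindows
from .landmarks import N_LANDMARKS, LandmarkFrame, LandmarkTrack, Side, validate_frame

__all__ = [
    "read_track_csv",
    "write_track_csv",
    "read_windows",
    "write_windows",
    "read_ranges",
    "write_ranges",
    "build_report",
    "write_report",
    "load_report",
    "report_csv_row",
    "detect_landmarks",
    "TrackFormatError",
    "DetectorContractError",
]

N_COLUMNS = 2 + 2 * N_LANDMARKS  # frame, time_s, x1..y68

REPORT_SCHEMA_VERSION = 1


class TrackFormatError(ValueError):
    """A trajectory file that violates the CSV contract."""


class DetectorContractError(RuntimeError):
    """A landmark backend that violates the adapter contract."""


def _side_to_str(side: Optional[Side]) -> str:
    return side.value if side is not None else "none"


def _side_from_str(s: str) -> Optional[Side]:
    return None if s in ("", "none") else Side(s)


def write_track_csv(track: LandmarkTrack, path: Union[str, Path]) -> None:
    """Write a track with metadata comments; floats round-trip exactly."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("# fpstage trajectory v1\n")
        fh.write(f"# subject_id={track.subject_id}\n")
        fh.write(f"# frames_per_second={track.frames_per_second!r}\n")
        fh.write(f"# affected_side={_side_to_str(track.affected_side)}\n")
        fh.write(f"# hb_label={track.hb_label or 'none'}\n")
        writer = csv.writer(fh)
        header = ["frame", "time_s"]
        for i in range(1, N_LANDMARKS + 1):
            header += [f"x{i}", f"y{i}"]
        writer.writerow(header)
        for f in track.frames:
            row = [f.frame_index, repr(float(f.time_s))]
            row += [repr(float(v)) for v in f.points.ravel()]
            writer.writerow(row)


def read_track_csv(
    path: Union[str, Path],
    subject_id: Optional[str] = None,
    affected_side: Optional[Side] = None,
    hb_label: Optional[str] = None,
    frames_per_second: Optional[float] = None,
) -> LandmarkTrack:
    """Parse and validate a trajectory CSV; explicit arguments override
    metadata found in the file's comment lines.  Parse errors cite the
    1-based line number."""
    path = Path(path)
    meta: dict[str, str] = {}
    frames: list[LandmarkFrame] = []
    header_seen = False
    last_index: Optional[int] = None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = next(csv.reader([line]))
            if not header_seen:
                if len(cells) != N_COLUMNS:
                    raise TrackFormatError(
                        f"{path.name}:{lineno}: expected {N_COLUMNS} columns "
                        f"(frame, time_s, x1..y68), got {len(cells)}"
                    )
                header_seen = True
                continue
            if len(cells) != N_COLUMNS:
                raise TrackFormatError(
                    f"{path.name}:{lineno}: expected {N_COLUMNS} columns, got {len(cells)}"
                )
            try:
                idx = int(cells[0])
                time_s = float(cells[1])
                coords = np.array([float(c) for c in cells[2:]], dtype=float)
            except ValueError as exc:
                raise TrackFormatError(f"{path.name}:{lineno}: non-numeric cell ({exc})") from None
            if last_index is not None and idx <= last_index:
                raise TrackFormatError(
                    f"{path.name}:{lineno}: frame index {idx} not strictly increasing "
                    f"(previous {last_index})"
                )
            last_index = idx
            frames.append(validate_frame(coords.reshape(-1, 2), frame_index=idx, time_s=time_s))
    if not header_seen:
        raise TrackFormatError(f"{path.name}: no header row found")
    if not frames:
        raise TrackFormatError(f"{path.name}: no data rows found")

    fps = frames_per_second if frames_per_second is not None else float(
        meta.get("frames_per_second", 30.0)
    )
    return LandmarkTrack(
        frames=frames,
        frames_per_second=fps,
        subject_id=subject_id if subject_id is not None else meta.get("subject_id", path.stem),
        affected_side=(
            affected_side
            if affected_side is not None
            else _side_from_str(meta.get("affected_side", "none"))
        ),
        hb_label=hb_label if hb_label is not None else (
            None if meta.get("hb_label", "none") == "none" else meta["hb_label"]
        ),
    )


# ---------------------------------------------------------------------------
# Windows / ranges JSON


def write_windows(windows: MovementWindows, path: Union[str, Path]) -> None:
    Path(path).write_text(windows.to_json() + "\n")


def read_windows(path: Union[str, Path]) -> MovementWindows:
    return MovementWindows.from_json_dict(json.loads(Path(path).read_text()))


def write_ranges(table: GradeRangeTable, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(table.to_json_dict(), indent=2) + "\n")


def read_ranges(path: Union[str, Path]) -> GradeRangeTable:
    """Load a user-supplied grade-range table (monotonicity validated)."""
    return GradeRangeTable.from_json_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Report


def _movement_dict(m: MovementAsymmetry) -> dict:
    return {
        "expression": m.expression.value,
        "feature": m.feature.value,
        "healthy_shift": m.healthy_shift,
        "affected_shift": m.affected_shift,
        "shift_difference": m.shift_difference,
        "asymmetry_index": None if np.isnan(m.asymmetry_index) else m.asymmetry_index,
    }


def build_report(
    track: LandmarkTrack,
    scale: Optional[ScaleCalibration],
    windows: MovementWindows,
    result: AsymmetryResult,
    assignment: GradeAssignment,
) -> dict:
    """Assemble the versioned analysis report."""
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool": {"name": "fpstage", "version": _version},
        "subject": {
            "subject_id": track.subject_id,
            "affected_side": _side_to_str(track.affected_side),
            "hb_label": track.hb_label,
            "n_frames": track.n_frames,
            "frames_per_second": track.frames_per_second,
        },
        "scale": None if scale is None else {"t_mm_per_px": scale.t, "source": scale.source},
        "windows": windows.to_json_dict(),
        "asymmetry": {
            "frown": _movement_dict(result.frown),
            "smile": _movement_dict(result.smile),
            "total_shift_difference": result.total_shift_difference,
            "total_asymmetry_index": (
                None if np.isnan(result.total_asymmetry_index) else result.total_asymmetry_index
            ),
            "unit": result.unit,
            "flags": sorted(result.flags),
        },
        "grading": {
            "combined": assignment.combined.value if assignment.combined else None,
            "primary_feature": assignment.primary_feature.value,
            "features": {
                fid.value: {
                    "grade": fg.grade.value if fg.grade else None,
                    "status": fg.status,
                    "note": fg.note,
                }
                for fid, fg in assignment.feature_grades.items()
            },
            "rationale": assignment.rationale,
        },
    }


def write_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def load_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def report_csv_row(report: dict) -> dict:
    """Flatten a report to the one-row CSV export."""
    asym = report["asymmetry"]
    return {
        "subject_id": report["subject"]["subject_id"],
        "affected_side": report["subject"]["affected_side"],
        "combined_grade": report["grading"]["combined"],
        "forehead_sd": asym["frown"]["shift_difference"],
        "mouth_sd": asym["smile"]["shift_difference"],
        "total_sd": asym["total_shift_difference"],
        "forehead_ai": asym["frown"]["asymmetry_index"],
        "mouth_ai": asym["smile"]["asymmetry_index"],
        "total_ai": asym["total_asymmetry_index"],
        "unit": asym["unit"],
        "flags": ";".join(asym["flags"]),
    }


# ---------------------------------------------------------------------------
# Detector adapter

#: Backend contract: image -> (68, 2) array of points (1-based numbering
#: order) or None when no face is found.
LandmarkBackend = Callable[[np.ndarray], Optional[np.ndarray]]


def detect_landmarks(
    source: Union[str, Path, Iterable[np.ndarray]],
    backend: LandmarkBackend,
    frames_per_second: float = 30.0,
    max_gap_s: float = 0.5,
    subject_id: str = "",
    affected_side: Optional[Side] = None,
) -> LandmarkTrack:
    """Run a landmark backend over video frames and assemble a track.

    ``source`` is an iterable of images, or a video path handed to
    ``imageio`` (optional dependency).  Frames where the backend reports no
    face are gap-filled by linear interpolation when the gap lasts at most
    ``max_gap_s``; a longer gap splits the track and raises.  A backend
    that returns anything but 68 points (or None) violates the contract.
    """
    if isinstance(source, (str, Path)):
        try:
            import imageio.v3 as iio
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "reading video files needs the 'video' extra (imageio)"
            ) from exc
        frames_iter: Iterable[np.ndarray] = iio.imiter(str(source))
    else:
        frames_iter = source

    detections: list[Optional[np.ndarray]] = []
    for image in frames_iter:
        pts = backend(image)
        if pts is None:
            detections.append(None)
            continue
        pts = np.asarray(pts, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise DetectorContractError(
                f"backend contract violation at frame {len(detections)}: "
                f"expected ({N_LANDMARKS}, 2) points or None, got shape {pts.shape}"
            )
        detections.append(pts)

    n = len(detections)
    if n == 0:
        raise DetectorContractError("backend produced no frames")
    missing = sum(d is None for d in detections)
    if missing * 2 >= n:
        raise DetectorContractError(
            f"undetectable subject: no face in {missing}/{n} frames"
        )

    max_gap = max(1, int(round(max_gap_s * frames_per_second)))
    # Trim leading/trailing gaps (nothing to interpolate against).
    first = next(i for i, d in enumerate(detections) if d is not None)
    last = max(i for i, d in enumerate(detections) if d is not None)
    frames: list[LandmarkFrame] = []
    i = first
    while i <= last:
        if detections[i] is not None:
            frames.append(
                validate_frame(detections[i], frame_index=i, time_s=i / frames_per_second)
            )
            i += 1
            continue
        j = i
        while detections[j] is None:
            j += 1
        gap = j - i
        if gap > max_gap:
            raise DetectorContractError(
                f"track split: no face for {gap} frames ({gap / frames_per_second:.2f} s) "
                f"at frames {i}..{j - 1}, exceeding the {max_gap_s} s gap limit"
            )
        prev_pts, next_pts = detections[i - 1], detections[j]
        for k in range(i, j):
            w = (k - (i - 1)) / (j - (i - 1))
            interp = (1 - w) * prev_pts + w * next_pts
            frames.append(validate_frame(interp, frame_index=k, time_s=k / frames_per_second))
        i = j
    return LandmarkTrack(
        frames=frames,
        frames_per_second=frames_per_second,
        subject_id=subject_id,
        affected_side=affected_side,
    )
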