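"""Synthetic 68-landmark trajectory generator with known ground truth.

Emulates the recording protocol the staging system expects: a frontal
video (default 18 s at 30 fps on a 640x480 px canvas, ~0.5 mm/px) in which
the subject first rests, then frowns the forehead, returns to rest, and
smiles.  Each expression displaces the relevant landmarks with a
raised-cosine rise / plateau / fall activation so that the true maximum is
attained exactly on the plateau; the affected hemiface performs the same
movement attenuated by the target asymmetry index.  Detector jitter is
modelled as i.i.d. Gaussian pixel noise on every coordinate, added before
calibration.

Every simulated track comes with a :class:`SimulationTruth` carrying the
exact movement windows, per-side shifts, shift differences and asymmetry
indices that a perfect pipeline should recover — with zero noise the full
pipeline inverts the simulator to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .asymmetry import CALIBRATED_GRADES, FeatureID, Grade, GradeRangeTable, packaged_ranges
from .calibration import ScaleCalibration
from .kinematics import Expression, MovementWindows
from .landmarks import LandmarkFrame, LandmarkTrack, Side, validate_frame

__all__ = [
    "FRAME_SIZE",
    "SimulationParams",
    "SimulationTruth",
    "SimulatedSubject",
    "neutral_template",
    "simulate_track",
    "grade_cohort",
]

#: Synthetic canvas (width, height) in pixels.
FRAME_SIZE = (640, 480)

_CX = FRAME_SIZE[0] / 2  # face midline

# Landmark ids (1-based) displaced by each expression, per side.  Side A is
# the image-left hemiface; the whole eyebrow moves when frowning, the mouth
# corner (outer and inner) when smiling.
_BROW_IDS = {Side.A: (18, 19, 20, 21, 22), Side.B: (23, 24, 25, 26, 27)}
_CORNER_IDS = {Side.A: (49, 61), Side.B: (55, 65)}
_SMILE_DIRECTION = {Side.A: -1.0, Side.B: +1.0}  # corners move laterally outward


def _template_points() -> np.ndarray:
    """Bilaterally symmetric neutral 68-point face (about x = 320)."""
    pts = np.zeros((68, 2))
    # jaw 1-17: half-ellipse from left temple over the chin to the right
    theta = np.pi * (1 - np.arange(17) / 16)
    pts[0:17, 0] = _CX + 100 * np.cos(theta)
    pts[0:17, 1] = 240 + 160 * np.sin(theta)
    # eyebrows 18-22 (A) and 23-27 (B), arched, apex at points 20/25
    arch = np.array([200.0, 196.0, 194.0, 196.0, 200.0])
    xa = np.array([245.0, 260.0, 275.0, 290.0, 305.0])
    pts[17:22] = np.column_stack([xa, arch])
    pts[22:27] = np.column_stack([2 * _CX - xa[::-1], arch[::-1]])
    # nose bridge 28-31 and nostril base 32-36
    pts[27:31] = np.column_stack([np.full(4, _CX), np.linspace(230, 280, 4)])
    pts[31:36] = np.column_stack([np.linspace(300, 340, 5), np.full(5, 300.0)])
    # eyes 37-42 (A) and 43-48 (B); 38/45 upper lids, 42/47 lower lids
    eye_a = np.array(
        [[255, 240], [270, 234], [285, 234], [298, 240], [285, 246], [270, 246]], dtype=float
    )
    pts[36:42] = eye_a
    mirrored = eye_a.copy()
    mirrored[:, 0] = 2 * _CX - mirrored[:, 0]
    pts[42:48] = mirrored[[3, 2, 1, 0, 5, 4]]  # keep ring order: inner->outer
    # outer lip 49-60; corners at 49 (A) and 55 (B)
    pts[48:60] = np.array(
        [
            [270, 340], [285, 332], [300, 328], [320, 326], [340, 328], [355, 332],
            [370, 340], [355, 350], [340, 356], [320, 358], [300, 356], [285, 350],
        ],
        dtype=float,
    )
    # inner lip 61-68; 63 is the mouth centre
    pts[60:68] = np.array(
        [
            [280, 340], [300, 336], [320, 334], [340, 336],
            [360, 340], [340, 346], [320, 348], [300, 346],
        ],
        dtype=float,
    )
    return pts


def neutral_template() -> LandmarkFrame:
    """A symmetric neutral face; both sides' feature gaps are exactly equal."""
    return validate_frame(_template_points(), frame_index=0, time_s=0.0)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; the defaults are the emulated study conditions.

    Amplitudes are the *healthy*-side excursions in mm; the affected side
    moves ``ai x amplitude``.  ``seed`` is mandatory: every randomised path
    must be reproducible.
    """

    seed: int
    frames_per_second: float = 30.0
    duration_s: float = 18.0
    rest_s: float = 3.0
    frown_amp: float = 8.0
    smile_amp: float = 6.0
    frown_ai: float = 1.0
    smile_ai: float = 1.0
    noise_sd_px: float = 0.3
    scale_t: float = 0.5
    affected_side: Optional[Side] = Side.B
    subject_id: str = "sim"
    hb_label: Optional[str] = None
    rise_s: float = 0.5
    plateau_s: float = 0.5
    inter_movement_rest_s: float = 3.0

    def __post_init__(self) -> None:
        for name in ("frames_per_second", "duration_s", "rest_s", "rise_s", "plateau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frown_amp", "smile_amp", "frown_ai", "smile_ai", "noise_sd_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.scale_t <= 0:
            raise ValueError("scale_t must be positive")
        event = 2 * self.rise_s + self.plateau_s
        needed = self.rest_s + 1.0 + 2 * event + self.inter_movement_rest_s + 0.5
        if self.duration_s < needed:
            raise ValueError(
                f"duration_s={self.duration_s} too short for the protocol "
                f"(needs >= {needed:.1f} s)"
            )

    @property
    def scale(self) -> ScaleCalibration:
        return ScaleCalibration(t=self.scale_t, source="explicit")


@dataclass(frozen=True)
class SimulationTruth:
    """Exact ground truth of a simulated track."""

    windows: MovementWindows
    healthy_shift: dict[Expression, float]  # mm
    affected_shift: dict[Expression, float]  # mm
    shift_difference: dict[Expression, float]  # mm
    asymmetry_index: dict[Expression, float]
    total_shift_difference: float
    total_asymmetry_index: float

    def to_json_dict(self) -> dict:
        return {
            "windows": self.windows.to_json_dict(),
            "healthy_shift": {e.value: v for e, v in self.healthy_shift.items()},
            "affected_shift": {e.value: v for e, v in self.affected_shift.items()},
            "shift_difference": {e.value: v for e, v in self.shift_difference.items()},
            "asymmetry_index": {e.value: v for e, v in self.asymmetry_index.items()},
            "total_shift_difference": self.total_shift_difference,
            "total_asymmetry_index": self.total_asymmetry_index,
        }


def _profile(times: np.ndarray, start: float, rise: float, plateau: float) -> np.ndarray:
    """Raised-cosine activation: 0 -> 1 over ``rise``, hold ``plateau``, back to 0.

    The plateau evaluates to exactly 1.0 so a noiseless maximum equals the
    injected amplitude bit-for-bit.
    """
    u = np.zeros_like(times)
    t = times - start
    rising = (t >= 0) & (t < rise)
    u[rising] = 0.5 * (1 - np.cos(np.pi * t[rising] / rise))
    hold = (t >= rise) & (t <= rise + plateau)
    u[hold] = 1.0
    falling = (t > rise + plateau) & (t < 2 * rise + plateau)
    u[falling] = 0.5 * (1 - np.cos(np.pi * (2 * rise + plateau - t[falling]) / rise))
    return u


def simulate_track(params: SimulationParams) -> tuple[LandmarkTrack, SimulationTruth]:
    """Generate one landmark track and its exact ground truth."""
    p = params
    fps = p.frames_per_second
    n = int(round(p.duration_s * fps))
    times = np.arange(n) / fps

    event_s = 2 * p.rise_s + p.plateau_s
    frown_start = p.rest_s + 1.0
    smile_start = frown_start + event_s + p.inter_movement_rest_s
    frown_u = _profile(times, frown_start, p.rise_s, p.plateau_s)
    smile_u = _profile(times, smile_start, p.rise_s, p.plateau_s)

    amp_px = {
        (Expression.FROWN, "healthy"): p.frown_amp / p.scale_t,
        (Expression.FROWN, "affected"): p.frown_ai * p.frown_amp / p.scale_t,
        (Expression.SMILE, "healthy"): p.smile_amp / p.scale_t,
        (Expression.SMILE, "affected"): p.smile_ai * p.smile_amp / p.scale_t,
    }

    def role(side: Side) -> str:
        if p.affected_side is None:
            return "healthy"
        return "affected" if side is p.affected_side else "healthy"

    base = _template_points()
    coords = np.broadcast_to(base, (n, 68, 2)).copy()
    for side in Side:
        a_frown = amp_px[(Expression.FROWN, role(side))]
        for pid in _BROW_IDS[side]:
            coords[:, pid - 1, 1] = base[pid - 1, 1] - a_frown * frown_u
        a_smile = amp_px[(Expression.SMILE, role(side))]
        for pid in _CORNER_IDS[side]:
            coords[:, pid - 1, 0] = base[pid - 1, 0] + _SMILE_DIRECTION[side] * a_smile * smile_u

    w, h = FRAME_SIZE
    if coords[..., 0].min() < 0 or coords[..., 0].max() >= w or coords[..., 1].min() < 0 or coords[..., 1].max() >= h:
        raise ValueError(
            f"amplitudes frown={p.frown_amp} mm / smile={p.smile_amp} mm push "
            f"landmarks outside the {w}x{h} frame"
        )

    if p.noise_sd_px > 0:
        rng = np.random.default_rng(p.seed)
        coords = coords + rng.normal(0.0, p.noise_sd_px, size=coords.shape)

    frames = [
        LandmarkFrame(frame_index=i, time_s=float(times[i]), points=coords[i])
        for i in range(n)
    ]
    track = LandmarkTrack(
        frames=frames,
        frames_per_second=fps,
        subject_id=p.subject_id,
        affected_side=p.affected_side,
        hb_label=p.hb_label,
    )

    windows = MovementWindows(
        rest=((0, int(round(p.rest_s * fps))),),
        movement={
            Expression.FROWN: (
                int(round(frown_start * fps)),
                int(round((frown_start + event_s) * fps)) + 1,
            ),
            Expression.SMILE: (
                int(round(smile_start * fps)),
                int(round((smile_start + event_s) * fps)) + 1,
            ),
        },
    ).validate(n)

    healthy = {Expression.FROWN: p.frown_amp, Expression.SMILE: p.smile_amp}
    affected = {
        Expression.FROWN: p.frown_ai * p.frown_amp,
        Expression.SMILE: p.smile_ai * p.smile_amp,
    }
    sd = {e: healthy[e] - affected[e] for e in Expression}
    ai = {
        e: (affected[e] / healthy[e]) if healthy[e] > 0 else math.nan for e in Expression
    }
    truth = SimulationTruth(
        windows=windows,
        healthy_shift=healthy,
        affected_shift=affected,
        shift_difference=sd,
        asymmetry_index=ai,
        total_shift_difference=sd[Expression.FROWN] + sd[Expression.SMILE],
        total_asymmetry_index=(ai[Expression.FROWN] + ai[Expression.SMILE]) / 2.0,
    )
    return track, truth


@dataclass(frozen=True)
class SimulatedSubject:
    """One cohort member: the track, its ground truth, and the planted grade."""

    track: LandmarkTrack
    truth: SimulationTruth
    grade: Grade


# Physiologically plausible cap on a healthy-side excursion; keeps sampled
# amplitude/AI combinations jointly realistic (a near-symmetric face cannot
# also have a huge shift difference).
_AMP_MAX_MM = 25.0


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi)) if hi > lo else lo


def grade_cohort(
    n_per_grade: int,
    table: Optional[GradeRangeTable] = None,
    seed: int = 0,
    noise_sd_px: float = 0.3,
    base_params: Optional[SimulationParams] = None,
) -> list[SimulatedSubject]:
    """Simulate a labelled cohort with per-grade target asymmetries.

    For each grade II-V, asymmetry-index targets are drawn uniformly inside
    the grade's calibrated AI intervals, and movement amplitudes are chosen
    so the expected shift differences land inside the grade's SD intervals
    (partials and total jointly).  Infeasible joint constraints raise a
    ``ValueError`` naming the grade and feature.
    """
    if n_per_grade < 0:
        raise ValueError("n_per_grade must be >= 0")
    if table is None:
        table = packaged_ranges()
    proto = base_params or SimulationParams(seed=0, noise_sd_px=noise_sd_px)
    rng = np.random.default_rng(seed)
    subjects: list[SimulatedSubject] = []

    for grade in CALIBRATED_GRADES:
        f_lo, f_hi = table.interval(FeatureID.FOREHEAD_SD, grade)
        m_lo, m_hi = table.interval(FeatureID.MOUTH_SD, grade)
        t_lo, t_hi = table.interval(FeatureID.TOTAL_SD, grade)
        for i in range(n_per_grade):
            ai_f = _uniform(rng, *table.interval(FeatureID.FOREHEAD_AI, grade))
            ai_m = _uniform(rng, *table.interval(FeatureID.MOUTH_AI, grade))
            sdf_hi = min(f_hi, _AMP_MAX_MM * (1 - ai_f))
            sdm_hi = min(m_hi, _AMP_MAX_MM * (1 - ai_m))
            if sdf_hi < f_lo:
                raise ValueError(
                    f"infeasible constraints for grade {grade.value}, FOREHEAD_SD: "
                    f"AI {ai_f:.3f} admits at most {sdf_hi:.2f} mm"
                )
            if sdm_hi < m_lo:
                raise ValueError(
                    f"infeasible constraints for grade {grade.value}, MOUTH_SD: "
                    f"AI {ai_m:.3f} admits at most {sdm_hi:.2f} mm"
                )
            tot_lo = max(t_lo, f_lo + m_lo)
            tot_hi = min(t_hi, sdf_hi + sdm_hi)
            if tot_hi < tot_lo:
                raise ValueError(
                    f"infeasible constraints for grade {grade.value}, TOTAL_SD"
                )
            total = _uniform(rng, tot_lo, tot_hi)
            sd_f = _uniform(rng, max(f_lo, total - sdm_hi), min(sdf_hi, total - m_lo))
            sd_m = total - sd_f
            params = replace(
                proto,
                seed=int(rng.integers(2**31)),
                frown_amp=sd_f / (1 - ai_f),
                smile_amp=sd_m / (1 - ai_m),
                frown_ai=ai_f,
                smile_ai=ai_m,
                noise_sd_px=noise_sd_px,
                affected_side=Side.A if rng.integers(2) == 0 else Side.B,
                subject_id=f"sim-HB{grade.value}-{i + 1:02d}",
                hb_label=grade.value,
            )
            track, truth = simulate_track(params)
            subjects.append(SimulatedSubject(track=track, truth=truth, grade=grade))
    return subjects
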