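# Methods

This note documents the measurement model, the calibrated staging tables,
the statistical conventions, and the design decisions behind `fpstage`,
together with what the synthetic-data tests do and do not demonstrate.

## Measurement model

**Landmarks.** Faces are represented as the standard 68-point
face-alignment landmark set, addressed 1-based. The staged points are
eyebrows 20/25, upper eyelid rims 38/45, mouth corners 49/55 and mouth
centre 63. Lower eyelid rims 42/47 are carried in the data model for
completeness but take no part in staging: eye-closure movements are
excluded because their contraction is hard to modulate voluntarily and
does not yield a discriminative asymmetry index. The two hemifaces are
labelled geometrically (A = image-left in the synthetic templates, B =
image-right); which side is *affected* is subject metadata supplied by the
clinician, never inferred from the landmark data — nothing in a landmark
file identifies anatomical left/right reliably.

**Feature distances.** Each expression is measured in the plane it acts
in: forehead frowning moves the brow vertically, so the forehead feature
is the absolute vertical eyebrow-to-upper-lid gap; smiling pulls the mouth
corner laterally, so the mouth feature is the absolute horizontal
corner-to-centre gap. Axis-projected distances are the default; a
Euclidean option exists (`projected=False`) but changes results only when
landmarks drift obliquely. Projected distances are invariant to rigid
translation of the face and to perturbations orthogonal to the measured
axis; they are *not* invariant to in-plane head rotation, which is assumed
negligible for a cooperating, frontally seated subject (a limitation, see
below).

**Calibration.** One scalar `t` (mm/px) converts pixel distances to mm:
`t = f[mm] / f[px]` for any feature of known size — a 5 mm adhesive
marker (the predecessor marker-based protocol), a known reference length,
or an explicit value. Asymmetry indices are ratios and need no
calibration; without `t`, shift differences are reported in px, flagged
`no-scale`, and the combined grade falls back to the asymmetry index.

**Shift.** For each movement and hemiface,
`shift = max(distance over the movement window) − mean(distance at rest)`.
Subtracting the resting mean removes the anatomical baseline so only true
excursion remains; a flaccid side may legitimately score ~0 or slightly
negative (flagged `negative-shift`). The maximum (not a percentile) is
used because the clinically reported quantity is the peak excursion; an
optional 95th-percentile robust mode exists for very noisy detectors but
is off by default. Note the statistical consequence: a maximum over an
n-frame window of a jittered signal is biased upward by roughly
`E[max of n N(0, σ_d)]`, where `σ_d = √2 · noise_sd_px · t` is the
per-frame distance noise. At 0.3 px jitter and t = 0.5 mm/px this is
≈ 0.4 mm per side; it largely cancels in shift *differences* (both sides
are biased alike) and enters asymmetry indices as an error of order
`bias · (1 − AI) / healthy_shift`.

**Windows.** Frame intervals are half-open `[a, b)` over 0-based frames
everywhere; landmark ids are 1-based — the asymmetry is deliberate
(frames are an engineering artefact, point numbering is a published
convention). Explicit window annotations (JSON) always take precedence
and mirror the clinical workflow of selecting frames of interest by hand.
Auto-detection is a convenience stand-in:

* *rest* — the maximal initial interval in which every feature series
  stays within `k·MAD` (k = 3) of its initial-second median. The interval
  ends at the first **sustained, sign-consistent** exceedance: 5
  consecutive frames beyond the band in the same direction in the same
  series. A single-frame criterion is useless in practice — at 0.3 px
  jitter a 3·MAD (≈ 2σ) excursion occurs within a few frames by chance,
  and a 30-frame MAD estimate is itself noisy — whereas a genuine
  movement onset departs monotonically in one direction. Minimum rest:
  0.5 s, else "no rest baseline" is raised.
* *movements* — a 1 s window centred on the post-rest global maximum of
  the forehead series (healthy side when known, else the two-side mean)
  for frowning, then likewise on the mouth series searched after the
  frown window, enforcing the protocol order frown-before-smile.
* Only the initial pre-movement still segment forms the baseline;
  post-movement returns to rest are excluded to avoid carry-over from
  incomplete relaxation.
* No smoothing is applied by default; an optional 3-frame moving median
  is available in the robust mode only.

## Staging

**Quantities.** Per movement: shift difference `SD = healthy − affected`
(mm, sign preserved) and asymmetry index `AI = affected / healthy`
(negative numerators clamped to 0 and flagged; healthy shifts below
ε = 1e-6 make the ratio undefined — NaN with an `unstable-ratio` flag,
never an exception). Totals: SDs summed; AIs *averaged*, which keeps the
total on the same 0–1–1.2 scale as the partial indices and as normal
faces (normals range ≈ 0.99–1.2). The mean-vs-sum choice is an affine
rescaling, so cohort ANOVA statistics are unaffected by it; `"sum"` is
available as a configuration.

**Grade ranges.** Six features (forehead/mouth/total × SD/AI) carry
closed per-grade intervals for HB II–V, packaged in
`fpstage/data/grade_ranges.json` from the Min/Max rows of a 40-patient
calibration cohort (10 per grade). Two provenance notes matter:

* the forehead-SD grade-II lower bound is 0.39 mm, not the printed 0.40 —
  one cohort member's printed value is 0.39 and the interval must cover
  its own cohort;
* total-AI intervals are not published; they are derived as per-patient
  means of the two partial indices over the same cohort (monotone and
  non-overlapping, asserted in tests).

SD intervals must increase and AI intervals decrease with grade, without
overlap; this is validated whenever a table is constructed or loaded, so
a user-supplied `--ranges` file inherits the same invariants.

**Assignment.** A value inside an interval takes that grade. A value in
the gap between adjacent intervals takes the grade with the nearest
boundary, ties to the more severe grade — clinically conservative; a
`refuse` mode returns "unclassifiable" instead for workflows that prefer
abstention. Values milder than grade II report `better-than-II`, values
beyond grade V report V with out-of-range status; grades I and VI are
outside the calibrated tables and are never extrapolated. The combined
grade follows the total SD when measurements are in mm, else the total
AI; the published description weighs movements "both individually and
together" without fixing a precedence, so privileging the total (with
every per-feature grade and any disagreement listed in the rationale) is
this package's documented choice.

## Cohort statistics

Group summaries are mean/max/min and sample SD (n−1). One-way
fixed-effects ANOVA: `F = (SS_b/(k−1)) / (SS_w/(N−k))`; the effect size
`R²` is eta-squared `SS_b/SS_total` (the "R²" that common ANOVA software
prints; no adjusted variant). Degenerate conventions: all values
identical → F = 0; zero within-group variance with distinct means →
F = +inf, both noted in the result. Display rounding is
half-away-from-zero to 2 decimals (`round_half_away`, decimal-based so
3.375 → 3.38 regardless of binary representation); raw values are always
retained.

The packaged calibration cohort (`fpstage/data/reference_cohort.json`)
stores the 40 patients' printed per-patient values and the tables' own
printed summary rows. Recomputation (`reference.audit_printed_summaries`)
reproduces 62 of the 80 summary cells exactly after rounding; 18 cells
disagree by exactly one unit in the last digit (pinned in the test
suite), and the smiling-movement and partial-AI ANOVA F values are not
recoverable from the printed 2-decimal inputs at all (recomputed 127.8 vs
107.7 printed for smiling, for example). These are recorded as
typesetting/rounding artefacts of the source tables, not matched; the
forehead and total shift-difference ANOVAs do reproduce (77.76 vs 78.02
and 180.36 vs 183.0, within 1.5%).

## Synthetic data

The generator emulates the recording protocol: 18 s at 30 fps (within the
15–20 s protocol) on a 640×480 px canvas at t = 0.5 mm/px, a bilaterally
symmetric neutral template, 3 s of rest, then frown, return to rest, then
smile. Activations are raised-cosine rise (0.5 s) / plateau (0.5 s) /
fall, so the true maximum is attained exactly on the plateau and a
noiseless pipeline inverts the generator to numerical precision. The
affected hemiface performs the same movement scaled by the target AI.
Detector jitter is i.i.d. Gaussian pixel noise on every coordinate, added
before calibration. Default healthy amplitudes for one-off tracks are
8 mm (frown) and 6 mm (smile), plausible mid-range excursions; the
per-grade cohort sampler instead draws AI targets uniformly inside each
grade's calibrated intervals and derives amplitudes from the SD intervals
via `amp = SD/(1−AI)` (jointly with the total-SD constraint, and capped
at 25 mm so near-symmetric faces are not assigned absurd excursions),
which is what the calibration cohort itself implies (≈ 2–20 mm).

What the simulator does **not** model: head motion and rotation, detector
dropouts or systematic landmark bias, movement latency differences
between sides, synkinetic coupling, and photorealistic appearance.
Passing closed-loop tests therefore demonstrates that the measurement,
asymmetry and staging arithmetic is correct and robust to additive
jitter — not that any particular landmark detector is accurate on real
palsy faces; for real video the detector adapter and the annotation
pathway carry that burden.

## Numerical choices and edge cases

* Exactly-constant rest series have MAD = 0; the band gets a 1e-12 floor
  so noiseless tracks detect cleanly.
* CSV trajectories write floats with `repr`, making write/read
  round-trips bit-exact; report JSON is schema-versioned and re-yields
  the exact feature values used for grading.
* Backend adapter: frames with no detected face are linearly
  interpolated when the gap is ≤ 0.5 s; longer gaps split the track (an
  error naming the gap), and a subject missing in ≥ 50% of frames is
  rejected as undetectable.
* Seeds are mandatory for every randomised path; identical parameters and
  seed give byte-identical trajectory files.

## Known limitations

* In-plane head rotation contaminates axis-projected distances; the
  package assumes stabilized frontal video and provides the Euclidean
  option rather than a registration step.
* The calibrated ranges come from a single 40-patient cohort; they are
  packaged as data with provenance and can be replaced wholesale via
  `--ranges` without code changes.
* The max-based excursion estimator is upward-biased under jitter (see
  above); at 0.3 px jitter this is immaterial for staging (grade recovery
  ≈ 99% in simulation) but asymmetry indices of very small movements
  (healthy shifts of a few mm) carry errors near the ±0.05 level.
* Grades I and VI, synkinesis, eye closure and static (resting) asymmetry
  are out of scope.
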