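# Methods

## The measurement chain

The pipeline estimates the seated whole-body centre of mass (CoM) of a
person working under simulated lunar gravity, from markerless multi-camera
video, and relates its pelvis-relative displacement to gravity level and
task by ordinary least squares. The stages, in data order:

2D keypoints (25 per frame and camera, OpenPose BODY_25 JSON) →
confidence-weighted DLT triangulation → segmental whole-body CoM →
pelvis-relative displacement per frame → endurance-time window means →
per-sex OLS.

## Segmental CoM model

Each modeled segment (i, j) contributes mass `m_ij` at
`P_i + k_ij (P_j − P_i)`, where `P_i` is the proximal joint and `k_ij` the
proximal CoM coefficient; the whole-body CoM is the mass-weighted mean
over segments, normalised by the summed modeled mass `M`. Segment mass
fractions are the Plagenhoef (1983) water-immersion statistics; the
sex-specific k values for forearm / upper arm / trunk are
0.430 / 0.436 / 0.630 (males) and 0.434 / 0.458 / 0.569 (females). The
trunk spans the hip joint (MidHip) to the shoulder line (Neck), the full
hip-to-shoulder distance being 100 % of trunk length.

The default modeled set is the upper body above the hip joint: trunk,
head+neck, both upper arms and both forearms (≈65 % / 62 % of male /
female body mass). Hands are not modeled: BODY_25 has no landmark distal
to the wrist, so a hand segment has no measurable axis; their ≈1.3 % of
body mass is omitted rather than invented. The head+neck coefficient
(0.55, both sexes, Neck→Nose axis) is a package default from standard
anthropometric tables. The table ships as plain YAML
(`lunarcom/data/segment_table.yaml`) and can be replaced wholesale.

Because fractions normalise out, CoM location is invariant to total body
mass; masses matter only for the ballast design.

## Axes and sign conventions

World frame: right-handed, X mediolateral, Y up (proximodistal), Z
anterior; units cm. Displacements are referenced to the pelvis keypoint:
`dY = pelvis_y − com_y` (a CoM *below* the pelvis is positive) and
`dZ = pelvis_z − com_z` (a CoM *behind* the pelvis is positive), so a
downward shift and a backward tilt with increasing gravity both appear as
positive regression coefficients. Both conventions are flippable.

A frame missing any required keypoint is excluded from window means, never
interpolated; the exclusion is visible in per-window frame counts.

## ET windows

A trial lasts its endurance time ET (min). Three windows are summarised:
`[0, w)`, `[ET/2 − w/2, ET/2 + w/2)` and `[ET − w, ET)`, with
`w = clamp(window_s, ·, 60 s)` (default 5 s). Windows are half-open so a
trial sampled at rate f contributes exactly `w·f` frames per window.
Window means of dY and dZ are the analysis observations; three per trial
are pooled as independent rows (matching the degrees of freedom of the
original per-sex OLS output; a CR1 cluster-robust SE option by participant
exists but is off by default).

## Hypogravity ballast model

A submerged segment of mass m and volume V, with an attached ballast of
mass `m_b` and density `ρ_b`, is in simulated lunar gravity when

    (m + m_b) g − ρ_w (V + m_b/ρ_b) g = m g_t,

giving `m_b = (m (g_t − g) + ρ_w V g) / (g (1 − ρ_w/ρ_b))`. Defaults:
g = 9.81, g_t = 1.626 m/s², fresh water ρ_w = 1000, lead
ρ_b = 11340 kg/m³. The ballast is treated as pure compensation hardware
(the right side is the *segment's* lunar weight); the alternative
accounting, with the ballast part of the simulated mass, is a constants
flag. A negative solution means the segment needs flotation, and the error
reports the required flotation mass; a head-compensation entry may use a
per-segment density override. Ballasts above 3 kg are flagged for added
moment of inertia (point-mass model `I = m_b r²`).

The drag criterion for slow dynamic tasks bounds the hand speed by
`v = sqrt(2 f W / (ρ_w C_d A))` with the drag force at most fraction f
(default 10 %) of a reference weight W. C_d and A have no published values
for this setup, so both are explicit parameters; the generator instead
caps its commanded hand speed directly at 47 cm/s.

## Multi-view geometry

Pinhole cameras with optional two-term radial distortion; calibration is
an input (plain YAML: K, R, t, distortion, image size) and is assumed
valid in-medium — underwater flat-port refraction is *not* modeled.
Triangulation is linear DLT on undistorted normalized rays, weighted by
detection confidence; keypoints with confidence 0 are undetected; fewer
than `min_views` (default 2) valid observations, or a rank-deficient
system, marks the keypoint invalid rather than raising. An optional
nonlinear reprojection refinement exists only as an independent oracle in
the tests; the default path is deterministic linear algebra. Frames are
matched across cameras by index with an optional constant per-camera
offset. When several people are detected, the person whose hip is nearest
the previous frame's hip is tracked (first frame: largest bounding box).

PCK counts predicted keypoints within `alpha ×` a reference distance
(default: annotated torso diagonal, alpha = 0.2) of their annotations.
The threshold is a parameter because published PCK figures rarely state
it; PCK values are screening diagnostics, not reproduction targets.

## Regression stage

Per sex and axis: `d = β₀ + β_g I(1 g) + β_task I(dynamic) + ε`, solved
closed-form via the normal equations, with classical SEs
`σ̂² (XᵀX)⁻¹`, two-sided t p-values, R², adjusted R², residual SE on
n − 3 df and the overall F. A constant indicator is dropped with a
warning; an exactly collinear design raises. The report grid prints
`coefficient stars (SE)` per cell plus fit statistics; the star legend is
configurable (default *** p < 0.01, ** p < 0.05) and exact p-values are
always printed alongside, so the legend is cosmetic. Shapiro–Wilk
(AS R94 / Royston, via scipy) is provided as a normality screen only — no
automatic branching to non-parametric methods.

## Synthetic-study generator

The generator defines the study conditions; every default is stated here
once and not tuned.

**Cohort.** 18 males / 14 females. Heights and masses are sex-specific
truncated normals — males N(1.83, 0.07) m and N(82.92, 13.02) kg, females
N(1.66, 0.06) m and N(56.19, 5.95) kg, truncated to the cohort-wide
ranges [1.54, 1.95] m and [43.8, 114.1] kg. Segment lengths scale with
height (upper arm 0.35/0.32 m, forearm 0.30/0.25 m at the mean heights)
and segment volumes with mass (torso 44.71/27.00, upper arm 2.70/1.48,
forearm 1.37/0.72 dm³), deterministically, so skeleton and buoyancy are
mutually consistent.

**Endurance times.** Log-normal around the per-cell means (min), CV 0.3:
static 1 kg 1.67/0.95 (1 g) and 7.73/6.21 (1/6 g), static 3 kg 0.85/0.34
and 2.65/0.65, dynamic 1 kg 1.30/0.80 and 14.93/9.34, dynamic 3 kg
0.79/0.35 and 2.16/0.82 (male/female). Only the means are published; the
log-normal shape and CV are package choices (ETs are positive and
right-skewed).

**Effect injection.** Window displacement targets are drawn at the level
the regression consumes:
`target = offset + β₀ + β_g I(1 g) + β_task I(dynamic) + N(0, σ)` per
axis, with the published per-sex models as defaults (male dY:
−8.47 + 17.06 g + 3.17 task, σ = 8.45; male dZ: 6.67 − 1.45 g − 2.17 task,
σ = 8.01; female dY: 5.70 + 5.87 g − 0.94 task, σ = 2.11; female dZ:
−3.77 + 6.02 g + 0.44 task, σ = 5.26; all cm). 114 male and 56 female
analysis rows (38 and 19 trials of three windows, round-robin over
gravity × task × load cells; the female table is trimmed by one row).

**Posture offsets.** The `offset` terms are constant posture baselines
(male dY −1.6, dZ −35.0; female dY −37.0, dZ +0.5 cm). They exist because
the *absolute* pelvis-relative CoM of a seated body lies on an annulus a
few tens of cm from the hip, whereas the published coefficients describe
*changes*; the offsets centre each sex's target cloud inside the
geometrically reachable set (females: upright posture, CoM ≈ 30 cm above
the hip; males: a deep forward lean, whose larger effect and noise scales
need the tangential freedom). An intercept offset is absorbed by the
fitted constant and leaves the gravity/task coefficients and residual SD
untouched.

**Inverse posing.** The seated template (hip at origin, legs seated,
25 BODY_25 keypoints) has two solved degrees of freedom: a trunk-flexion
("slouch") scale s ∈ [0.45, 1.15] of the hip-shoulder distance, which
sets the CoM distance from the hip, and a torso pitch, which sets its
direction. Since the posed CoM is exactly a rotation of the body-frame
CoM `c(s)`, the solve is a 1-D monotone root find on `‖c(s)‖` followed by
a closed-form angle alignment — posing then measuring back through the
segmental CoM reproduces the target to < 1e-6 cm. Two *rigid* DOFs alone
span only a thin annulus; the slouch scale is what lets dY move
independently of dZ, mimicking spinal flexion. Targets whose radius still
falls outside the reachable annulus raise an error in single-trial use;
study-level generation projects them onto the annulus, preserving the
proximodistal coordinate whenever possible (so the acceptance-checked dY
quantities are unaffected; only the non-targeted male dZ noise is
clipped, at roughly its 1.5 σ tail). Realized values are bookkept in
`truth.csv` with a `clipped` flag.

**Tasks.** Static: right arm outstretched anterior, left hanging; frames
within a window share the solved pose plus 0.05° SD pitch jitter.
Dynamic: the loaded forearm oscillates sinusoidally over a 60° range of
motion with the wrist speed capped at 0.9 × 47 cm/s; the pose is solved
with the oscillation's time-averaged forearm direction (`J₀(A)`
shortening), so window means still reproduce targets. Frames are
generated only inside the three ET windows — the regression consumes
window means, so intermediate frames would carry no information.

**Rendering.** Three cameras on a 2 m circle, 120° apart, 1920×1080,
focal 1100 px, 30 Hz default; Gaussian pixel noise (1 px SD), confidence
dropout (2 %), written in the reader's JSON dialect
(`study/<trial>/cam{1..3}/frame_%06d.json` plus `calib.yaml`, `meta.csv`,
`truth.csv`). Per-trial random streams are spawned from the master seed:
output trees are byte-identical for a fixed seed.

## What the synthetic data does and does not show

The generator exercises the full chain — JSON parsing, triangulation
noise, keypoint dropout, segmental CoM, windowing, OLS — against known
truth, so passing tests demonstrate the *computational* correctness and
calibration of every stage. It does not emulate real underwater optics
(refraction, turbidity), genuine OpenPose failure modes (left/right
swaps, identity switches), camera desynchronisation, within-trial fatigue
dynamics, or between-participant postural idiosyncrasies; the published
male residual SD (8.45 cm) in particular exceeds what a single rigid
template can express as posture, which is why the generator treats it as
target-level noise rather than claiming a postural mechanism. Agreement
on synthetic data therefore validates the method, not any claim about new
experimental data.

## Numerical choices and problem sizes

* Triangulation: SVD on the stacked DLT system; degenerate if the third
  singular value falls below 1e-10 of the first.
* Ballast balance: closed form, residual verified by substitution
  (~1e-13 N worst case over random segments).
* Pose solve: Brent's method, xtol 1e-12, with the realized CoM recomputed
  from the solved pose so bookkeeping is exact by construction.
* OLS: normal equations (3-column designs are far from ill-conditioned);
  cross-checked against a QR oracle and statsmodels to 1e-9 in tests.
* Default test/acceptance problem sizes: rendered studies run at 10 Hz
  with 3 s windows (window means are insensitive to frame density — a
  window mean over 30 frames differs from the 150-frame version by ≪ the
  residual SD); replicate-level recovery uses 200 seeded replicates at
  the full 114/56 row counts with geometric realization but no rendering.

## Known limitations

* No refraction model: calibration must already be valid in-medium.
* Hands and lower limbs are outside the default CoM segment set (seated,
  pelvis-referenced analysis); both can be added via a custom table.
* Repeated windows are pooled as independent observations by default;
  cluster-robust SEs are available but change the printed SE scale.
* The PCK threshold, drag C_d·A, ET dispersion and head+neck k are
  explicit parameters with documented defaults, not published values.
* CoM velocity/energetics (work, metabolic cost) are out of scope.
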