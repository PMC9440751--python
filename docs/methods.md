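# Methods

This note documents the models, conventions and numerical choices behind
`morphoflight`, and what its synthetic tests do and do not establish about
real data.

## Coordinate and angle conventions

The world frame is right-handed with z up and gravity along −z.  The body
frame has x along the long axis toward the head, y to the animal's left and
z dorsal; body orientation is the intrinsic Z(yaw)–Y(pitch)–X(roll)
rotation with pitch positive nose-up, so pitch 90° points the body straight
up.  All user-facing angles are degrees, speeds m/s, masses g and wing
areas cm² (both wing pairs); internal computation is SI with radians.

Each wing's stroke plane is the plane normal to the body long axis through
that wing's hinge; hinges are fixed in the body frame within a flight.
Wing posture is the Euler triple (Φ, θ, H): stroke angle Φ sweeps the span
axis within the stroke plane (zero at the lateral direction, positive
dorsal — the zero reference within the stroke plane is not standardized in
the field, so this choice is a package convention), deviation θ elevates
the span axis out of the plane (positive toward the head), and rotation H
pitches the chord about the span axis (zero when the wing plane coincides
with the stroke plane).  For the canonical left wing the composition is
`R = Rx(Φ) · Rz(−θ) · Ry(H)` on the reference span (+y) and chord (−z,
ventral) axes; right wings are mirror conjugates through the body x–z
plane, so bilaterally symmetric strokes read out mirrored Φ, θ and
identical angles of attack by construction.  At θ = ±90° the stroke angle
is undefined and flagged rather than fabricated.

## Stereo geometry

Cameras are the classical 11-coefficient DLT (linear pinhole; pixels are
assumed undistorted upstream).  Calibration solves the homogeneous system
by SVD after Hartley pre-normalization of both 3D and pixel coordinates,
then fixes the 12th (constant) coefficient to 1; at least 6 non-coplanar
control points are required, and coplanarity is detected from the singular
values of the centered point cloud (rank tolerance 1e-9 relative).  The
sign of the projection denominator at the calibration points defines the
in-front convention, letting the projector flag points behind a camera.
Triangulation is the linear (algebraic) least-squares solution over all
cameras that see a point; frames with fewer than two views are reported
missing, never interpolated.  Wand pairs of known separation provide the
field-standard accuracy diagnostic.  Wand-only autocalibration and bundle
adjustment are out of scope; camera synchronization is assumed exact.

## Trajectory smoothing and climb metrics

The body track is smoothed per axis by a linear Kalman filter with state
(position, velocity, acceleration), a constant-acceleration transition and
white-jerk process noise of spectral density `process_noise`
(default 500 m²·s⁻⁵ — large enough not to over-smooth manoeuvring flight at
1–2 m/s and 240 Hz), followed by a Rauch–Tung–Striebel fixed-interval
backward pass (the data are offline, so the smoother is the right
estimator).  The observation noise SD defaults to 2 mm, the typical
triangulation residual of a 0.5 px rig at ~1 m; pass the measured rig value
when available.  The filter is initialized from a quadratic through the
first three observed frames, which makes recovery exact on tracks the model
matches (constant velocity or acceleration); missing frames are handled by
prediction-only steps.

A wingbeat runs from one highest-upstroke reversal to the next, downstroke
first; reversal frames are inputs (as digitized), though the simulator
supplies its truth reversals.  Per wingbeat the package reports wingbeat
frequency, horizontal path length, signed net vertical displacement, 3D
path length, the wingbeat means of horizontal speed magnitude, vertical
velocity and total speed, and the climb angle computed from the
wingbeat-mean speeds, `γ = atan(U_ver/U_hor)` — not the mean of per-frame
angles.  `U_hor` is the magnitude of the horizontal velocity vector, so γ
stays in [−90°, 90°].  Ensemble dynamics resample each downstroke and
upstroke linearly onto a common phase grid and carry a pointwise Student-t
95% CI across wingbeats (the CI unit — wingbeats — is a package choice; a
single wingbeat returns a mean with the CI flagged undefined).

## Blade-element wing kinematics

Wings are rigid flat plates defined by a 41-point planar outline with the
hinge at the local origin; each wing is cut into 10 equal spanwise strips
and each strip is represented by its area centroid (polygon clipping via
shapely).  Element velocities are central differences of the centroid world
positions at the frame rate (one-sided at series ends), so they combine
body translation and wing rotation exactly for rigid motion.  The angle of
attack is the angle between the wing plane and the element velocity,
`α = asin(|v·n̂|/|v|) ∈ [0°, 90°]`, undefined (flagged) at zero element
speed.  The wingbeat angle of attack averages the blade-element mean α at
the temporal midpoints of the downstroke and the upstroke (both
half-strokes contribute; a flagged midpoint falls back to the nearest valid
frame and the fallback is recorded), then averages left/right within each
wing pair.  `U_wingbeat` is the mean element speed over all elements of all
four wings across the wingbeat; `A_Φ = max(Φ) − min(Φ)`.

When poses are recovered from reconstructed landmarks rather than given,
the body long axis comes from the head–tail line and the lateral axis from
the left–right hinge lines (both wing pairs averaged — the hinge baseline
is short, so roll is the noisiest body angle), wing orientations are
Kabsch fits of the rigid outline to the reconstructed landmarks, and the
resulting angle series are Savitzky–Golay filtered (window 11 frames,
order 3 by default; the wingbeat period is ~48 frames at 240 Hz, so the
filter suppresses frame-to-frame digitization jitter without flattening
the stroke) before any velocity differencing.

## Aerodynamic model

The thrust scaling is `T/mg = ½ ρ U_wing² (S/mg) C_Tα α` with α in
radians: quadratic in wing speed, linear in air density, weight-normalized
wing area, angle of attack and the angle-of-attack-specific thrust
coefficient.  The ½ dynamic-pressure factor and the small-angle-linear
thrust coefficient `C_T = C_Tα·α` are the conventional blade-element
forms; C_Tα defaults to 1 rad⁻¹ and is configurable because no measured
value exists for these wings.  ρ defaults to 1.17 kg·m⁻³ (warm air at
~450 m elevation); g = 9.81 m·s⁻².  The steady-climb balance checks
`(T/mg)·sin(angle) = 1` vertically and `(T/mg)·cos(angle) = drag/mg`
horizontally.  The helicopter (body-fixed force vectoring) hypothesis is
tested as an OLS regression of climb angle on body pitch; any fixed offset
between body axis and force axis only shifts the intercept.

## Statistics

The sequential ANOVA is a Type-I decomposition with factors entered in the
stated order (microhabitat first, then species, individual, flight,
wingbeat index), each factor's SS being the drop in residual SS when its
dummies enter and its df the rank gained; F tests use the final residual
mean square.  All factors are fixed effects; with hierarchical (random)
variance at the species/individual/flight levels the habitat F test is
anticonservative — a known property of the fixed-effect treatment, which is
why the calibration tests use an iid-error null.  A mixed model is
deliberately out of scope.  MANOVA uses Wilks' λ = det(W)/det(W+B) with
Rao's F approximation.  The phylogenetic ANOVA compares the observed
one-way F of species means against F statistics of traits simulated under
Brownian motion on the supplied tree (default 10,000 simulations, +1
p-value correction; the BM rate is estimated from the tips by GLS, though F
is scale-free so the rate only sets the null sample's scale).  Branch
lengths must come from the user; unit lengths are the documented fallback.
The Wilcoxon rank-sum p-value is exact by enumeration up to 25 combined
observations without ties, otherwise a tie-corrected normal approximation
without continuity correction (so identical samples give p = 1).  Percent
contrasts are `100·(a−b)/b`, rounded to the reporting precision.  No
multiple-testing correction is applied across the ANOVA battery.

## The synthetic-data generator

The simulator emulates the study conditions: 240 frames/s, three orthogonal
~1000 px-focal cameras at ~1 m, a ~5 Hz wingbeat, stroke amplitude 114°
(peak-to-peak), climb angles near 40° at ~1.4 m/s, body pitch ~55°, and
0.5 px digitization noise.  Wing profiles are minimal periodic kinematics:
cosine stroke (so reversals fall on frames), double-frequency sinusoidal
deviation about a backward-shifted mean (hindwings −48°), and a rotation
angle flipping sign between half-strokes.  Body velocity is evaluated
analytically from the climb-angle and speed profiles and integrated on a
16× sub-frame grid (exact for constant profiles); acceleration is the
analytic derivative.  Truth per-wingbeat metrics are computed from the
truth trajectory by the same definitions the pipeline uses, so consistency
is exact by construction and recovery errors isolate measurement effects.

Cohorts are multi-level Gaussian: each base metric (horizontal and vertical
speed, wingbeat frequency, mass, wing area) is group mean + species +
individual + flight + wingbeat effects, the configured total SD being split
across levels by a variance partition (default 15/15/15/55%); species
effects are correlated by Brownian motion on a seven-species tree with a
canopy clade of two species (fixed, arbitrary ultrametric branch lengths of
depth 3).  Group means and SDs default to the published canopy/understory
summaries; derived metrics (total speed, climb angle, distances) are
computed per wingbeat from the base draws, which both induces the physical
correlations among the eight metrics and makes the derived group means
emerge rather than being imposed (e.g. mean climb angles near 46.7°/36.5°
arise from the configured speed components).  Default cohort sizes are 120
canopy and 90 understory wingbeats across 2 + 5 species — the same order as
the study's 106 + 77.

What the generator does *not* emulate: wing deformation (real wings flex
substantially; the rigid flat plate is a deliberate simplification), lens
distortion, digitization outliers or dropped frames, air motion in the
arena (still air assumed), within-wingbeat speed modulation, and any
non-Gaussian or skewed trait distributions.  Passing synthetic-recovery
tests therefore demonstrates correctness of the measurement chain under
the stated noise model, not robustness to those real-world effects.

## Problem sizes and runtimes

The test suite and the acceptance script use: three 5 Hz wingbeats at
240 Hz (145 frames) for end-to-end recovery; 50-point calibration sets and
1000-point triangulation ensembles; 50 random replicates for the smoothing
benchmark; 1000 (tests) or 500 (script) Monte-Carlo replicates for the
type-I calibrations with 199 Brownian simulations per phylogenetic test;
and n = 120 for the regression-shape checks, ten times the study's 12
tracked wingbeats to keep the sampling variance of R² well inside the
tolerance.  Everything runs in seconds to a few minutes on one CPU, and
every stochastic step takes an explicit seed.

## Known limitations

* Fixed-effect sequential ANOVA inflates the habitat test under true
  hierarchical variance (see above); conclusions on real data should rely
  on the phylogenetic test or a mixed model fitted elsewhere.
* DLT front/behind discrimination for externally supplied coefficient files
  assumes the standard positive-denominator convention.
* Wing pose recovery requires visible hinge, tip and outline landmarks in
  at least two cameras per frame; occlusion handling is limited to
  NaN-propagation.
* The thrust model is a scaling relation for regression, not a force
  time-history; no unsteady mechanisms are represented.
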