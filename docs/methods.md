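# Methods

This note documents the models, conventions and numerical choices
behind `bellkin`, in the order the pipeline applies them.

## Scope and assumptions

The pipeline treats the analysis as planar: one pair of opposing bell
segments is assumed perpendicular to the optical axis, and only roll —
rotation about the optical axis — is corrected. Out-of-plane rotation
(about the camera's x- or y-axis) projects information away and cannot
be recovered from a single view; sequences where it is non-negligible
are outside the method's domain. Digitization itself (video decoding,
edge clicking) is upstream of the package: the inputs are per-frame
outline points, a background reference track and a near-apex marker
track, all in pixels.

Frame timing follows `t = (frame − first_frame) · stride / fps`
(defaults 25 fps, stride 5, i.e. 0.2 s between digitized frames).
Pixel rows are flipped to a y-up convention on ingest (`y_down`,
default true for image-derived data).

## Magnification correction

Two multiplicative per-frame scales are estimated, both equal to 1 on
the first frame:

* **Reference scale** `s_ref(j) = |x_r(1) − x_c| / |x_r(j) − x_c|`,
  where `x_r` is the background landmark's x-position and `x_c` the
  frame-center x. This assumes the camera keeps the animal centered and
  moves only along the optical axis, so the landmark's offset from
  center is proportional to magnification. Only the x-displacement is
  used; the construction is symmetric and could equally use y. A
  landmark at the frame center makes the scale undefined and is
  rejected. Scaling is applied about the frame center; the center's
  y-coordinate only shifts the frames rigidly and is irrelevant after
  apex-rooting.
* **Arclength linear-fit scale.** Straight swimming is cyclic, so the
  exumbrella arclength must repeat at every full contraction. After
  `s_ref`, a least-squares line `L(t) = α + βt` through the
  contracted-instant arclengths captures the residual drift of the
  animal relative to the camera, assumed linear over the record;
  `s_lf(j) = L_fit(t_1)/L_fit(t_j)` removes it. At least two contracted
  instants are required; a fit implying non-positive arclength anywhere
  in the record is rejected.

The two scales remove exactly a planted magnification of the form
zoom(t) · (1 + r·t) when the zoom is what the reference point sees —
this is the generator's camera model and the basis of the recovery
tests.

## Apex, roll and the body frame

The apex is found by projecting the marker onto the outline and
walking `apex_offset` pixels along the outline (sign configurable; the
offset is measured manually on the first frame). The marker must lie
within `max(2·apex_offset, 5 % of outline length)` of the outline. The
outline splits into apex-rooted left and right half profiles, with the
interpolated apex inserted as the first vertex of each.

Roll uses the near-apex region, which deforms least during swimming:
points within ±`top_fraction` (default 0.24) of each half's arclength
from the apex enter an ordinary least-squares line fit; `θ = arctan m`.
OLS is exactly rotation-equivariant only for collinear points; for the
shallow, nearly symmetric apex region the equivariance bias is second
order in the apex opening angle and the recovery tests bound it well
below the 0.5° tolerance used throughout. Vertically collinear fit
points (slope undefined) are an error. The transform to body
coordinates translates the apex to the origin and applies the active
rotation by −θ; with θ = 90° the point (1, 0) maps to (0, −1).

## Smoothing and resampling

Each half profile is converted to polar coordinates about the apex and
the radius is filtered against the *sample index* with a second-order
Butterworth low-pass at `filter_cutoff_fraction` of Nyquist (default
0.20), applied forward-backward so the filter is zero-phase and does
not shift material points in arclength. The index, not the geometric
angle, is the filtering axis because the margin can travel over the
apex during deep relaxation, making the geometric angle non-monotone.
The apex sample has radius 0 by construction and is excluded from the
filter; both endpoints are retained exactly. At least 9 points are
required for stable edge padding.

Resampling fits a cubic spline parameterized by cumulative chord
arclength to each coordinate and evaluates it at arclength fractions
`k/(n−1)`, `k = 0..n−1` (default `resample_n = 51`, indexed b = 0 at
the apex to b = 50 at the margin). Uniform-arclength indexing assumes
the exumbrella deforms equally along its length, so a fixed b addresses
the same material point over time. Finally all profiles are divided by
the relaxed half arclength of cycle 1 (mean of the two sides, taken
from `relaxed_frame` or the maximum-arclength frame), making positions
dimensionless.

## Discretization

* **Curvature.** Signed discrete curvature of each interior point is
  the reciprocal circumradius of its neighbor triple,
  `|κ| = 4A/(fgh)`, signed by turn direction (the unsigned circumcircle
  alone cannot distinguish peaks from valleys). Collinear triples give
  0; coincident points are an error. The derivative dκ/ds uses central
  differences over cumulative arclength. Candidate nodes are the
  linear-interpolated zero crossings of the across-frame mean
  derivative. Two noise guards apply: crossings whose two flanking
  derivative samples are both below 1e-3 of the derivative peak are
  ignored, and if the derivative peak itself is below 1e-6 of
  `max|κ̄|/L` the curve is treated as constant-curvature with no
  candidates. Across-frame variance uses the n−1 divisor.
* **Anatomical.** Fixed landmarks at 0/40/64/88/100 % of half
  arclength, bounding the central disk, circular muscles, radial
  muscles and flap. No nodes are placed inside the flap: its
  deformation is passive and, in a robotic analog, achievable by a
  passive material.
* **Error-minimizing.** The discrepancy of one profile against a chord
  model is `E_j = (Σ segment areas)/L_j`, each segment area being the
  absolute shoelace area of the closed polygon formed by the profile
  arc between two nodes and their chord; `E = Σ_j E_j` over all
  profiles and both sides. The normalization by the per-profile
  arclength makes E dimensionless and is this package's convention —
  published error values computed under a different normalization are
  not directly comparable. With endpoints fixed at 0 and 100 %, the
  optimal interior nodes on a percentage grid (default step 2 %, chosen
  so the 51-point sampling puts grid nodes on sample points) are found
  by dynamic programming over the additive per-segment costs — exactly
  equivalent to exhaustive enumeration, which a test verifies on small
  instances — with ties broken toward the lexicographically smallest
  fraction tuple. Candidate-restricted optimization (for the curvature
  method) enumerates subsets outright.

## Kinematic model

Deflection angles: φ₁ is the angle of segment 1 below the body-frame
horizontal (positive downward); φ_k for k ≥ 2 is the CCW-signed turn
from segment k−1 to segment k. This convention is this package's
choice; it makes forward kinematics from the apex invert the
extraction exactly, and angle channels are unwrapped over time so no
±180° jumps remain.

Each channel of one clipped cycle (re-originated at contraction onset;
a window spanning the whole record is rotated cyclically) is tiled
nine times and fitted by linear least squares on
{1, cos(nωt), sin(nωt)}, n = 1..order. Least squares rather than an
FFT because a cycle holds only ~27 samples; for an exactly periodic
signal the tiling leaves coefficients unchanged. The default order is
8 — high enough to track the plateau-and-ramp channels at 27 samples
per cycle while staying well below the rank limit (2·order+1 samples
required). Fitting is refused on rank-deficient designs.

Phase detection takes the actively driven channel (the circular-muscle
angle, which decreases during contraction) over one cycle starting at
contraction onset. Velocities are interval finite differences passed
through a 3-point median (suppresses isolated noise flips without
moving a monotone run's boundary by more than one interval):
contraction is the initial run with negative velocity of magnitude
≥ ε·peak (default ε = 0.05; raise toward ~0.1 for noisy digitizations),
cruise follows while |v| < ε·peak, relaxation is the remainder, and the
three intervals partition the period exactly. Both duty-cycle
conventions are reported: contraction/T (cruise counted as relaxation)
and (contraction+cruise)/T (the figure relevant when actuators must be
powered to hold the contracted shape).

## Derived metrics

Node trajectory loops use the signed shoelace area of each node's
closed path over a cycle; orientation (outer vs inner path during
contraction) is labelled by comparing mean apex distance during the
contraction and relaxation phases. Margin excursion is the per-axis
absolute displacement of the margin between paired relaxed and
contracted instants, averaged over sides and cycles (endpoint frames,
not phase means). The subumbrella volume revolves the region bounded
by the profile, the apex axis, and the horizontal line through the
profile's minimum y; the boundary line integral `V = |π ∮ x² dy|`
(exact per straight edge) is used instead of disk stacking because the
profile becomes multi-valued in y during deep relaxation. Left and
right half volumes are averaged; both the margin radius and its double
are exposed. A profile crossing the rotation axis beyond 1e-3 of its
arclength is rejected.

## The synthetic swimmer

The generator poses a four-segment chain with trapezoidal
(ramp–plateau–ramp) angle waveforms — chosen over sinusoids so phase
durations are exactly specifiable — with per-segment lag, rounds the
joints with circular fillets (radius 0.04, required to be under half
the shortest segment; real bells have no kinks and the curvature method
needs smooth extrema), and samples the curve uniformly in arclength.
Defaults: anatomical node fractions; phase durations 2 / 1 / 2.4 s
(period 5.4 s); lags 0, 0, 0.6, 0.9 s for disk, circular muscles,
radial muscles and flap; rest deflections (5, −10, −10, −8)° and
amplitudes (12, −28, −14, −22)°, a moderate contraction that keeps the
margin direction near −110° when fully contracted; arclength pulsation
+5 % at full contraction. The amplitudes are simplified monophasic
versions of the biphasic muscle motions seen in real animals; the lag
structure and phase durations are the biologically documented ones.
The camera applies zoom (linear ramp to `zoom_total`, seen by the
reference point), drift (1 + rate·t, invisible to the reference), roll
(sinusoid or ramp) about the apex image, and Gaussian pixel noise
behind a single integer seed.

What the generator does *not* emulate — and what passing recovery
tests therefore do not demonstrate — includes: non-axisymmetric
stabilization kinematics, out-of-plane rotation, nonlinear magnification
drift, manual-digitization point spacing irregularity beyond isotropic
Gaussian noise, cycle-to-cycle gait variability, and the flap's 3-D
folding. Recovery results on synthetic scenes bound the pipeline's
numerical behavior under the stated camera model, not its accuracy on
arbitrary field footage.

## Known limitations

* The arclength linear-fit scale assumes drift linear in time over the
  whole record; curved drift leaves a residual it cannot see.
* Roll estimation inherits OLS's small rotation-equivariance bias and
  degrades if the apex region deforms asymmetrically.
* Phase boundaries are threshold-based; on noisy channels the cruise
  plateau shrinks unless ε is raised or phases are detected on the
  Fourier-smoothed channel.
* The error measure E depends on the stated per-profile normalization;
  only orderings between node sets evaluated under the same convention
  are meaningful.
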