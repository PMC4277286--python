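# bellkin

Accurate 2-D bell kinematics of large, freely swimming jellyfish from
hand-held in-situ video.

Large medusae such as *Cyanea capillata* (lion's mane jellyfish, up to
~2 m bell diameter) cannot be brought into a filming tank, so their
swimming must be recorded in the open ocean by a free-swimming diver.
Such footage violates the assumptions of standard 2-D kinematography:
the camera approaches the animal (magnification grows), the animal
drifts relative to the camera (residual scale change), and the body
rolls about the optical axis. `bellkin` takes manually digitized
exumbrella outlines (e.g. from ImageJ point-clicking every few frames)
plus two auxiliary tracks — a fixed background reference point and a
near-apex body marker — and turns them into corrected, body-frame,
constant-scale bell profiles that support quantitative biomechanics:
segment-level gait analysis, periodic kinematic models, and subumbrella
volume estimation. It is aimed at comparative biomechanists and at
engineers building jellyfish-inspired vehicles who need a
time-dependent model of the whole bell over a swimming cycle.

## Method

**Scale correction.** With the animal kept centered in frame, a
background landmark's distance from the frame center grows in
proportion to the magnification, so multiplying frame-*j* coordinates
by `s_j = |x_r(1) − x_c| / |x_r(j) − x_c|` restores the frame-1 scale.
The residual drift of the animal relative to the camera is removed by
exploiting cyclic swimming: the exumbrella arclength
`L = Σ √(Δx² + Δy²)` must repeat at every full contraction, so a linear
fit through the contracted-instant arclengths yields a second per-frame
scale `L_fit(t_1)/L_fit(t_j)`.

**Body frame.** The bell apex is located from the marker track plus a
fixed arclength offset, and the outline is split into apex-rooted left
and right half profiles. The region within ±24 % of each half's
arclength around the apex deforms least during swimming; the
least-squares line through those points gives the roll angle
`θ = arctan m`, and rotating by −θ about the apex moves the profile
into body coordinates. Profiles are then low-pass filtered
(second-order Butterworth at 20 % of Nyquist, zero phase, on the polar
radius about the apex), cubic-spline resampled to N_b = 51 points
uniform in arclength, and normalized by the relaxed half arclength of
cycle 1.

**Discretization.** Nodes along the bell are placed three ways:
(i) *curvature* — discrete signed curvature from the circumcircle of
consecutive point triples, `|κ| = 4A/(fgh)`, with candidates where
`dκ̄/ds = 0`; (ii) *anatomical* — the landmarks of the swimming
apparatus (coronal joint/circular muscles 40 %, radial muscles 64 %,
flap root 88 %, margin 100 %); (iii) *optimized* — the node set
minimizing the area error `E = Σ_j (area between profile j and its
chord model)/L_j`, found exactly on a 2 % grid.

**Gait model.** Segment lengths `l_k(t)` and deflection angles
`φ_k(t)` are fitted per channel with a truncated Fourier series
`a_0 + Σ_n a_n cos(nωt) + b_n sin(nωt)`, `ω = 2π/T`, after clipping one
cycle to start at contraction onset and tiling it nine times. Phase
structure (contraction / cruise / relaxation), duty cycles under both
conventions, node trajectory looping, and the subumbrella volume of
revolution `V = |π ∮ x² dy|` are derived from the corrected profiles.

Because real footage of this kind is proprietary, the package ships a
first-class synthetic swimmer (`bellkin.synthetic`): a four-segment
bell with lagged trapezoidal angle waveforms, pulsating exumbrella
arclength, and a camera model with zoom, drift, roll, and pixel noise —
so every pipeline stage has a parameter-recovery oracle.

## Worked example

Simulate two swimming cycles seen through a camera that zooms 1.25×,
rolls ±5°, and adds 0.2 px of digitization noise; then run the full
pipeline:

```
$ bellkin simulate --out scene --cycles 2 --zoom 1.25 --roll 5 --noise 0.2 --seed 3
wrote scene (55 frames) to scene
$ bellkin correct --points scene/points.csv --tracks scene/tracks.csv \
      --config scene/config.yaml --out halves.csv
wrote 110 half profiles to halves.csv
scale range s_total = 0.7979 .. 1.0000
$ bellkin discretize --halves halves.csv --method optimize --segments 4 --out model.json
nodes [0.0, 40.0, 64.0, 88.0, 100.0] with E = 0.1410
$ bellkin phases --halves halves.csv --model model.json --period 5.4 --eps 0.08
contraction 2.20 s, cruise 0.60 s, relaxation 2.60 s
duty cycle 40.7% (51.9% counting cruise as contraction); frequency 0.185 Hz
$ bellkin trajectories --halves halves.csv --model model.json --out loops.csv
node   0.0%: loop area +0.00000
node  40.0%: loop area -0.00009
node  64.0%: loop area -0.00039
node  88.0%: loop area -0.00887
node 100.0%: loop area -0.02827
```

Reading the output: the scale correction shrinks late frames by up to
~20 % to undo the camera's approach; the error-minimizing search lands
exactly on the anatomical joints planted by the generator (40/64/88 %),
with dimensionless area error E = 0.141 summed over all 110 half
profiles; the detected phases recover the planted 2 s contraction, 1 s
cruise, 2.4 s relaxation to within a sample or two of the 0.2 s frame
spacing (frequency 0.185 Hz); and loop areas grow toward the margin —
the lagging passive flap makes the bell tip sweep an outer path during
contraction and an inner path during relaxation, the hysteresis that
distinguishes rowing propulsion from simple jetting.

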