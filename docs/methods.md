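# Methods

## Problem and model

Small intestinal motility is quantified from 3D cine-MRI (here: coronal
bFFE-style geometry, ~1.4 × 1.4 × 2.5 mm voxels, 1 volume/s, ≈16 usable
frames after discarding the first two contrast-artifact volumes) by relating
estimated motion to the geometry of a segment centerline. The measured
quantity is the signed velocity of luminal content along the gut axis,
*v(s, t)* = (**u**(x(s), t) · **t̂**(s)) / Δt, where **u** is the
frame-to-frame displacement after common-mode suppression and **t̂** the
local unit tangent. Two aggregates summarise a segment: the mean velocity
(net peristalsis; sign follows the centerline orientation, which is
arbitrary with respect to the proximal–distal axis) and the mean absolute
velocity (motility magnitude). By construction |⟨v⟩| ≤ ⟨|v|⟩, with equality
only for perfectly unidirectional motion.

Note this is *luminal content* velocity, not peristaltic wave speed: the
tangential velocity of the intestinal wall itself is zero, so these
averages are systematically below wave velocities reported by manometric or
gastric cine-MRI methods.

## Registration

Deformation between frames is represented by two sinusoidal coordinate
networks (forward and backward maps) evaluated on world coordinates
normalised to the ROI bounding box, with displacement output scaled to
millimetres. Objective per mini-batch of ROI points:

- **NCC** between source intensities at the batch and target intensities at
  the mapped batch (global within the batch, not windowed — the window
  choice is open; global is the simplest consistent reading and behaves
  well in a 40 mm tube).
- **Symmetric Jacobian penalty** mean (det J − 1)² of each map's
  finite-difference Jacobian (central differences, h = 0.5 mm). Computing
  the Jacobian from extra forward evaluations keeps backpropagation
  first-order.
- **Cycle consistency** mean ‖b(x + f(x)) + f(x)‖² in both directions.

Optimisation: Adam under a one-cycle learning-rate policy. The **full
profile** mirrors the method's published schedule (1500 iterations,
3 × 256 network, ω₀ = 30, weights NCC 1.0 / Jacobian 0.05 / cycle 1.0,
max LR 1e-4). The **reduced profile** used by the test suite and the
acceptance script (300 iterations, 3 × 64 network, batch 128, max LR 1e-3,
ω₀ = 15, cycle weight 0.1) was calibrated on translation and flow phantoms:
at a 300-iteration budget the full-strength cycle term shrinks the
displacement field towards zero before the image term converges, and the
lower frequency scale favours the smooth fields the reduced problems
contain. The backend is implemented in NumPy with hand-written
backpropagation; it is deterministic given its seed (network init, batch
sampling and within-voxel jitter all derive from one generator).

The backend contract is minimal (`register(vol_a, vol_b, roi, purpose)`
returning forward/backward displacement callables plus diagnostics), so a
classical deformable method could be substituted. The **oracle backend**
wraps the phantom's exact displacement; its backward map is obtained by
fixed-point inversion (tolerance 1e-4 mm). For `purpose="propagation"`
(direct-to-reference registrations used to carry the centerline through
time) the oracle returns the motion of the tube *geometry* only (common
mode and wall deformation): an ideal tube tracker does not follow content
flowing through a stationary tube, and sustained flow would otherwise
advect the centerline off the end of the segment.

## Common-mode suppression

The suppressed displacement at a centerline point is the inner-disc mean
minus the outer-disc mean of the forward displacement (inner ⌀ 0.5 mm /
16 samples, outer ⌀ 30 mm / 256 samples, both area-normalised means so the
common component cancels with equal weight). Discs lie in the plane
orthogonal to the local tangent; the sampling pattern is a deterministic
sunflower spiral plus its point reflection, so the pattern mean is exactly
zero, uniform fields cancel to machine precision, and fields linear in
position average exactly to their centre value. The disc basis is built
from the *unsigned* tangent direction, so flipping the centerline
orientation reuses identical sample points and negates every velocity
exactly. The outer region is a full disc rather than an annulus; at these
radii the difference is an area fraction of (0.5/30)² ≈ 0.03%. Samples
falling outside the ROI or field of view are clipped; a point whose disc
coverage drops below 50% is flagged boundary-unreliable (flagged points are
retained in the map by default, and `aggregate_metrics` can exclude them).

## Centerline geometry and propagation

Centerlines live in world millimetres and are resampled to a uniform 1 mm
arc-length step (finer than the in-plane voxel size; makes the 8 mm
smoothing window an odd 9-tap kernel). Tangents are central differences of
neighbouring resampled points (one-sided at the ends), normalised to unit
length. Resampling is idempotent: an input already uniform at the step is
returned unchanged (tolerance 2e-3·step absorbs the chord-vs-arc
discrepancy a previous pass introduces on curves).

Propagation samples each frame's direct-to-reference displacement at the
reference points, smooths along arc length (8 mm centered moving average,
truncated and renormalised at the ends) and then across time (3 s window,
i.e. 3 taps at 1 s), and adds the result to the reference points. One model
per frame is expected; the reference frame's own (identically zero)
displacement participates in the temporal average as a legitimate sample.
A truncated 3-tap average necessarily attenuates periodic motion
(transfer (1 + 2cos ωΔt)/3) and lags at the sequence ends by about half a
frame's motion, so tracking accuracy statements assume drift that is slow
relative to the window — which breath-hold residual motion is.

## Phantom

The generator synthesises, analytically per frame, a bright tube (lumen
intensity 1.0, background 0.2, smooth ~1 mm wall transition) on a darker
textured background:

- **Geometry**: default gentle S-curve spanning the grid at mid-depth,
  lumen radius 7.5 mm (so the 30 mm suppression disc clears the lumen);
  grids 128 × 128 × 14 at 1.4 × 1.4 × 2.5 mm with 16 frames ("acquisition"
  scale) or 64 × 64 × 14 with 8 frames ("compact").
- **Luminal flow**: `flow_profile(s, t)` prescribes the peak (centerline)
  axial speed; the radial profile is Poiseuille-like, v(r) = v₀(1 − (r/R)²)
  (no-slip at the wall — the wall's tangential velocity is zero). Advection
  is discrete-time (forward-Euler per frame on a dense arc grid, per radial
  shell), and the ground-truth oracle reports exactly that step, so
  synthesis and oracle agree by construction; composed pairwise truths
  equal direct multi-frame truths to 1e-6 mm.
- **Texture**: periodic band-limited speckle along the tube, wavelengths
  7–40 mm, contrast 0.5. The band is physical: per-frame advection of a
  few millimetres must stay well inside the texture correlation length or
  intraluminal optical flow is unobservable to any registration. The
  background carries weak smooth 3D speckle (amplitude 0.05, wavelengths
  10–30 mm) that moves rigidly with the common mode — surroundings must be
  visible for common-mode motion to be estimable at all.
- **Common mode**: the `non_motile` preset uses a slow bulk drift,
  0.5·3 mm·(1 − cos 2πt/10 s) along an oblique direction — a subject
  settling during a breath-hold: zero velocity at t = 0, peak excursion
  3 mm, slow relative to the 3 s temporal smoothing window.
- **Presets**: `motile_forward` / `motile_backward` (±2 mm/s constant peak
  flow), `non_motile` (drift only), `bidirectional` (2.5·sin(2πt/8 s) mm/s,
  zero-mean back-and-forth). Motile presets omit the drift so that each
  study condition isolates one mechanism.
- All randomness flows from a single seed; identical configs are
  bit-identical.

What the phantom does **not** model: MR physics (coils, SENSE, partial
Fourier), through-wall deformation of surrounding loops, segment-dependent
flow profiles interacting with wall waves (when both are enabled the radial
flow factor uses the resting radius), and realistic texture statistics of
mannitol-filled bowel. Passing phantom tests therefore demonstrates the
correctness of the estimation/suppression/aggregation chain and the
achievable behaviour of the registration on well-posed inputs — not
clinical performance.

## Classification and evaluation

The motility threshold (on ⟨|v|⟩) and the two peristalsis cut points (on
⟨v⟩, fitted on reference-motile records only) are found by exhaustive
search over midpoints of consecutive sorted values, maximising training
accuracy; ties take the lowest cut, making fitting deterministic. The
"<50% motile" and "not motile" rater classes merge into one negative class.
Prediction is serial: segments at or below the motility threshold are
non-motile regardless of mean velocity. Cross-validation is five-fold and
grouped by subject (seeded subject shuffle, round-robin deal — balanced by
subject count), so no subject informs the thresholds applied to it. AUC and
Cohen's kappa delegate to scikit-learn behind the module surface; the test
suite cross-checks both against exhaustive pair-enumeration and
contingency-formula oracles. The two-sample comparison of cohort mean
absolute velocities uses Student's t-test (equal-variance by default,
Welch optional), two-sided, with significance at p < 0.001. Cohort
percentages are rounded half-up to integer percent.

Exclusion filters run in the documented order — length (> 4 cm), duplicates
(keep the longer of a pair; a direct mutual `duplicate_of` pair is a legal
encoding, longer chains that close on themselves are an error), then
rater-flagged extraction failures — and report a tally per category.

## Problem sizes and numerical choices

The test suite and acceptance script run oracle-backend recovery at the
full acquisition scale (128 × 128 × 14 × 16) and trained-backend recovery
on compact 64 × 64 × 14 phantoms with two frames and the reduced
registration profile; the synthetic classification cohort uses forty
48 × 48 × 14 segments (4 frames, oracle backend, two segments per subject,
±20% flow-speed jitter). Fixed-point inversion tolerance 1e-4 mm; Jacobian
finite-difference step 0.5 mm; disc sampling as above; all moving averages
centered/truncated. Degenerate inputs (single-point centerlines, coincident
nodes, zero-length segments, non-axis-aligned NIfTI affines, single-class
training sets, constant identical label vectors for kappa) raise typed
errors rather than returning silently wrong numbers.

## Known limitations

- The centerline propagation contract follows content motion wherever
  content and geometry motion coincide at the centerline; under sustained
  strong unidirectional flow a trained backend will partially advect the
  centerline with the content (the oracle backend models the ideal tube
  tracker instead). Velocities near segment ends are unreliable when
  material crosses the segment boundary, mirroring the field-of-view
  ambiguity of real acquisitions; affected points are coverage-flagged.
- The suppressed centerline velocity underestimates the peak luminal speed
  by the outer-disc leakage factor (≈ 12.5% at default radii with parabolic
  flow); the metrics are therefore comparable between segments but are not
  calibrated absolute flow speeds.
- The reduced registration profile is tuned for compact phantoms; the full
  1500-iteration profile mirrors the published schedule but is not
  exercised at acquisition scale inside the test budget.
- Orientation of a segment is arbitrary, so the sign of the mean velocity
  is meaningful only relative to the chosen centerline direction.
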