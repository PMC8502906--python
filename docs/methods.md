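# Methods

## Problem and scope

The package models intrafractional motion of the male pelvis: the slow,
non-periodic drift of the prostate over ten to fifteen minutes, driven by
bladder filling and rectal motion. The intended workflow is a short dynamic
series acquired at the start of a treatment session, from which a
patient-specific linear motion model is learned and then evaluated on the
later frames of the same session. No real dynamic MR data ship with the
package; a synthetic phantom with exactly known ground-truth motion stands
in for them, which is what makes every stage independently testable.

## Synthetic phantom

Three ellipsoidal organs (prostate, bladder, rectum) sit in a 96 mm
field of view at 1×1×2 mm voxels (in-plane finer than through-plane, as in
axial MR; a coarser 1.5×1.5×3 mm grid is used for the multi-subject
sweeps). Intensities are MR-flavoured — bright urine-filled bladder,
intermediate prostate, dark gas-filled rectum over a soft-tissue
background — with sigmoid edge ramps (1.2 mm), a low-frequency cosine
texture that travels with the anatomy, and additive Gaussian noise
(σ = 0.02 on a unit intensity range) that does not.

Motion is defined as an analytic forward displacement field
`u(p, t)` (reference coordinates → frame *t*, mm) built from three
kernels:

* **bladder filling** — radial expansion, linear ramp from the bladder
  centre to the configured per-frame growth at the surface
  (0.13 mm/frame by default), Gaussian falloff outside;
* **rectal drift** — anterior translation with a plateau inside the rectum
  and Gaussian falloff, amplitude slightly super-linear in time
  (filling accelerates; exponent 1.6, 0.11 mm/frame average);
* **prostate drift** — rigid translation coupled linearly to the bladder
  and rectal amplitudes (0.35 and 0.45) plus a small independent
  "relaxation" term with a √t profile (0.12 mm total).

Because the three amplitude profiles differ in time, the series spans a
low-dimensional but not rank-one motion space: one dominant drift mode
plus smaller secondary modes, with registration noise filling the rest of
the spectrum — qualitatively the structure reported for real subjects.

Frames are rendered by inverting the analytic map per voxel (fixed-point
iteration on the continuous function, converged to 10⁻⁴ mm) and
evaluating the analytic reference intensity there, so images, masks and
ground-truth fields are mutually consistent with no resampling chain. Every
ground-truth field is checked for a positive Jacobian determinant;
amplitudes that fold the deformation are rejected with the offending
frame named.

Default amplitudes were calibrated once, on the ground-truth fields alone,
so that roughly a fifth of the joint-boundary voxels move more than 1 mm
across the late (validation) frames — the regime the method is meant for,
where much of the motion is sub-voxel but the tail is clinically relevant.
Per-subject variation draws amplitude scale factors (0.5–1.5) and prostate
drift directions per subject.

What the phantom deliberately does **not** model: MR physics and scanner
artefacts, anatomically realistic organ shapes, sliding interfaces,
periodic (respiratory/peristaltic) motion, and interior organ texture
detail. Passing tests therefore demonstrate correctness of the pipeline's
mathematics and its behaviour under realistic noise and drift magnitudes —
not segmentation robustness or registration accuracy on clinical images.

## Registration

A variational intensity-conservation flow of the Horn–Schunck family:
linearised brightness-constancy data term plus quadratic smoothness
penalty, solved by the classic Jacobi-style iteration with a
spacing-weighted neighbour average (anisotropic voxels are handled in
physical units throughout; fields are stored in mm). The solver runs
coarse-to-fine on a Gaussian pyramid (three levels, factor 2) and is
*stopped at half resolution*: the finest level is never optimised, the
field is linearly upsampled to the full grid, which acts as a final
smoothing step appropriate for motion-model input. Within each level the
moving image is re-warped by the current field (8 warps × 20 inner
iterations by default) so displacements beyond the linearisation range
are captured incrementally; the accumulated field is smoothed with a
1-voxel Gaussian after each warp, which prevents the increments from
random-walking on image noise.

Defaults (regularisation weight α = 0.015 on unit-normalised intensities,
160 iterations/level) were tuned on the phantom's oracle cases: an
identity pair must stay below 0.05 mm mean field magnitude, a 2 mm
translation must be recovered within 0.5 mm on organ interiors, and
ground-truth phantom fields within one voxel at the segmentation boundary.
The backward transform for inverse-consistency checks is computed by a
second registration with the roles swapped, not by numerical inversion.

Caveat recorded during development: with the incremental-warp scheme the
full-resolution dissimilarity is *not* monotone in the iteration budget
(more iterations can trade a slightly worse warped-image MSE for a
smoother field). The property that does hold, and is tested, is that the
single-level, single-warp solver monotonically decreases its own
variational energy.

## Overlap metrics

DICE is the standard 2|A∩B|/(|A|+|B|). "Average Hausdorff" is read as the
symmetric average of the two directed mean nearest-neighbour distances
between boundary-voxel sets (6-connectivity boundaries, physical mm); the
one-sided variant would be a one-line change, the symmetric choice is
isolated in one function. The inverse-consistency VME composes the forward
and backward fields voxelwise (linear interpolation of the backward field
at the forward-displaced position) and averages the residual magnitude
over the segmented region.

Binary masks are warped by softening the rasterised indicator with a
0.8-voxel Gaussian, interpolating linearly and re-thresholding at 0.5.
Plain nearest-neighbour warping carries up to half-voxel staircase error,
which on 2–3 mm slices dominates every overlap score of interest; the
anti-aliased variant recovers an approximately sub-voxel surface position
and is used everywhere a mask is deformed. An exactly zero field returns
the mask unchanged.

## Motion model

PCA is performed only on the segmentation-boundary voxels of the reference
frame (boundary = mask voxels with a 6-neighbour outside), because organ
motion is captured there while registration output inside large
homogeneous regions (bladder lumen) is unreliable. The joint model uses
the union of the per-organ boundaries; weights are optimised jointly and
per-organ numbers are obtained by restricting the residuals to each
organ's boundary subset.

Observations are the training fields' boundary values stacked voxel-major
(xyz innermost, 3N entries). The decomposition uses the SVD of the centred
observation matrix; eigenvalues are those of the sample covariance
(denominator n−1). Components are unit-norm over the stacked vector,
signs fixed so the first nonzero entry is positive, and eigenvalues below
10⁻¹² of the larger of the top eigenvalue and the mean squared observation
are treated as numerical rank and dropped (the second guard makes a set of
identical training fields yield an empty spectrum rather than one
rounding-noise component).

Optimal weights are projections of the centred field onto the components.
These minimise the mean **squared** boundary residual; the mean unsquared
residual (which is what gets reported, in mm, matching how such results
are usually quoted) can differ from the optimum by ~10⁻⁴ mm and is not
exactly monotone in the component count. Optimality and monotonicity
checks therefore score the squared residual — available via
`residuals(..., squared=True)` — while all reported numbers remain
unsquared millimetres.

The train/validation protocol is fixed: the first five displacement fields
train, the remaining four consecutive fields validate; sub-models use
prefixes of the training set (2–5 fields). No leave-one-out — the drift is
non-periodic, so temporal extrapolation is the honest test.

## Inversion and model-predicted segmentations

The model predicts displacement only on the boundary and in the
reference→moving direction. To deform the reference segmentation into a
predicted segmentation, the boundary field is first extended into a band
(±6 mm) by normalised Gaussian-kernel (Nadaraya–Watson) averaging of the
boundary values (σ = 3 mm, computed by separable convolution; exact at
boundary voxels, exact for constant fields, zero outside the band), then
inverted by the fixed-point iteration `v ← −u(r + v)` (tolerance 0.01 mm,
50 iterations max; exact for constant fields after one pass, a contraction
whenever ‖∇u‖ < 1). The reference masks are pulled back through the
inverse and scored with DICE against the actual frame masks.

The band edge is a discontinuity where the contraction argument fails; a
few edge voxels can oscillate just above tolerance indefinitely. For
segmentation warping, convergence is therefore scored over the inner half
of the band, where the deformed surface actually lies; the standalone
`invert_field` keeps the global criterion and flags non-convergence
honestly.

## Experiment orchestration and problem sizes

The default study runs nine subjects at 64×64×32 voxels
(1.5×1.5×3 mm) — small enough that the full pipeline (9 forward + 9
backward registrations, model sweeps and ~36 inversion-based segmentation
predictions per subject) completes in a few minutes on one CPU, while
keeping all organ surfaces several voxels thick. Mean residuals are
reported per validation frame (voxels-then-frames); the >1 mm fraction and
the cumulative frequency curves pool voxels across validation frames —
both aggregations are emitted since either reading of a "mean over the
validation set" is defensible. All randomness flows from a single seed
through per-subject seeds below 2³¹; reports are bit-reproducible.

## Known limitations

* The model lives on the segmentation boundary only; nothing is claimed
  about interior dose-relevant displacement.
* The phantom's motion space is genuinely low-rank, so the model explains
  it almost completely (residuals ≈ 0.2 mm, >1 mm fraction ≈ 0 after
  fitting); real anatomy leaves a larger unexplained floor. The qualitative
  orderings (more training data helps, accuracy saturates at one-two
  components, the model reduces the >1 mm tail) are the transferable
  findings, not the absolute residual values.
* Horn–Schunck flow assumes intensity conservation; it is exercised here
  only with additive Gaussian noise, not with bias fields or through-plane
  signal changes.
* One global model per subject: organ-specific weight optimisation and
  inter-subject (population) modelling are out of scope.
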