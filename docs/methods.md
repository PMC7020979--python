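# Methods

This note documents the models implemented in `dirprop`, their assumptions,
the tunable parameters that matter, and the design choices made where the
underlying procedures were described only loosely in the literature the
toolkit emulates.

## Geometry and data model

Volumes are axis-aligned 3D scalar grids with voxel spacing and origin in
mm; the world coordinate of voxel `(i, j, k)` is `origin + index * spacing`
(0-based). Organ masks are boolean volumes on the exact grid of their image.
A structure's *surface* is the set of voxel centers of foreground voxels
with at least one background 6-neighbour, the grid border counting as
background. All distances are Euclidean distances in mm between
surface-voxel centers; no sub-voxel surface interpolation is performed. I/O
is NIfTI-1 via nibabel (diagonal affines only; the NIfTI header stores the
affine in float32, which bounds geometry round-trip precision).

## Similarity metrics

HD, MDA, DSC and JI are defined in the README. Two conventions deserve
mention:

* **MDA** is the *pooled symmetric* mean: the mean over the union of both
  directed nearest-neighbour distance sets, weighted by point counts.
  One-sided means are exposed (`directed_mean_distances`) for sensitivity
  checks.
* **JI = DSC/(2−DSC)** holds exactly per pair (it is an algebraic identity
  on voxel counts) but *not* for averages across fractions — tabulated mean
  DSC and mean JI cannot be converted into each other.

Nearest-neighbour distances use a k-d tree; the test suite checks the
implementation against an O(N²) brute-force oracle to 1e-9 mm on random
masks, and overlap ratios against direct voxel counting.

## Registration

The daily (fraction) image is FIXED and the planning CT is MOVING. A
deformation field stores one displacement u(x) in mm per fixed-grid voxel
with the pull-back convention: the moving-image location corresponding to
fixed voxel x is `x + u(x)`, and the total estimated map after rigid
composition is `T_rigid(x + u(x))`. This propagates planning contours onto
the daily grid with a single mask interpolation. (The alternative — treating
the pCT as fixed — would require inverting the field to move contours
forward; the chosen convention avoids that.)

**Rigid (6 DOF).** Normalized cross-correlation maximized by a Powell search
over three pyramid levels (downsampling 4/2/1). Three details matter in
practice and are deliberate:

* NCC is evaluated on a *fixed central crop* (default 10 mm margin) with
  clamped sampling. A parameter-dependent overlap mask would let the
  optimizer "improve" the score by pushing poorly matched edge voxels out
  of the evaluated region (a shrinking-overlap bias).
* Both images are smoothed slightly (σ = 0.8 voxel) at every level
  including the finest. Without this, linear interpolation averages the
  moving image's noise at sub-voxel offsets and NCC acquires spurious
  optima half a voxel from the truth.
* The search is fully deterministic (no stochastic sampling); identical
  inputs give bit-identical transforms.

**Free-form.** The displacement field is a cubic B-spline on an integer
voxel-stride control lattice per pyramid level (default control-point
spacings 32/16/8 mm, downsampling 4/2/1). The objective is mean squared
intensity difference, divided by the fixed image's variance so the scale is
comparable across modalities and raw/normalized intensities, plus a
first-difference penalty on control coefficients (weight `lam`, default
3e-4) that approximates λ‖∇u‖². Each level is minimized with L-BFGS-B using
the analytic adjoint of the B-spline synthesis for the gradient; levels are
additive (each refines the upsampled field of the previous). The recorded
per-level objective log is monotone non-increasing.

* **NIB** z-scores both images with mean/SD computed inside an *eroded*
  body mask (smoothed HU > −300, two erosions). Erosion keeps
  modality-dependent partial-volume voxels at the body outline out of the
  statistics; without it the normalized images acquire a global offset
  between CTOR and CBCT and the objective loses its modality invariance.
* **DIR-Profile stand-in** uses raw HU (no z-scoring) and a hard cap on the
  *total* displacement at each control point, `cap_frac` × the level's
  control-point spacing (default 0.2, i.e. 1.6 mm at the finest level).
  The cap applies to the inherited coarse-level field plus the level's own
  coefficients, so the allowed warp tightens with resolution — a genuine
  "proximity limitation". An earlier variant capping only each level's
  increment never binds at phantom deformation scales (a +60% bladder fill
  moves the boundary ≈3.4 mm, under a 0.4 × 8 mm per-level cap) and cannot
  reproduce the under-warping failure mode; the total-displacement cap
  with 0.2 does, while leaving small deformations (≤ the cap) essentially
  identical to NIB (DSC difference < 0.001 at +10% fill).

These registration algorithms are stand-ins for commercial algorithm
*classes* known only from one-sentence descriptions; the similarity measure,
regularizer, optimizer and constraint values are this package's own choices
and no numerical equivalence with any vendor product is claimed.

**Propagation** interpolates the 0/1 planning mask linearly at
`T_rigid(x + u(x))` and thresholds at 0.5 (one interpolation pass;
smoother surfaces than nearest-neighbour). Coordinates within half a voxel
of the mask's border clamp onto it so an ε-overshoot cannot erase a border
slice; farther outside is background.

**Shadowed NIB** adds a scalar (default +700 HU, raising soft tissue to
bone-like density; a `set` mode is also exposed) to the organ interiors of
*both* the fraction (manual contours) and the pCT (planning contours), then
runs rigid + NIB on the enhanced pair. Enhancing both sides is an
interpretation: an intensity-matching objective requires corresponding
contrast in both images for the enhanced interiors to act as a
correspondence target. With shift 0 the procedure reduces bit-for-bit to
plain NIB.

## Mixed-effects model

For metric value y of subject i, algorithm series k, fraction f:
`y = Xβ + b_i + e`, with `b_i ~ N(0, σ_b²)`, residual variance σ², and
`Corr(e_j, e_j') = ρ^|f_j − f_j'|` within a series. AR(1) indexed by
fraction *lag* handles first-five-then-weekly schedules without imputation.
When a subject contributes several series (two algorithms, or two organs),
serial correlation applies within each series and series share only the
subject intercept — a literal lag-0 correlation across series would make
the covariance singular, which is why `compare_algorithms` forms one series
per algorithm × organ trajectory.

Fitting is maximum likelihood (REML optional). The total variance is
profiled out analytically, leaving a two-parameter search over
(log σ_b²/σ², atanh ρ) by a deterministic Nelder-Mead simplex from three
fixed starting points; subjects sharing a schedule pattern share one
Cholesky factor per likelihood evaluation. Inference is Wald-type:
z = β̂/SE with SE from the GLS information matrix, two-sided normal p-values
and CI = β̂ ± 1.96·SE. Degenerate limits are honest: with ρ and the variance
ratio fixed at zero the fit reproduces OLS exactly, and a perfectly
explained response returns zero-width intervals. The test suite cross-checks
β and the log-likelihood against an independent mixed-model implementation
(statsmodels MixedLM) in the random-intercept case.

Calibration, measured by the acceptance script at the cohort's own scale
(20 subjects): parameter recovery within Monte-Carlo error and CI coverage
≈94–95% over 200 replicates (20 × 23, ρ = 0.5), and type-I error ≈6% over
1000 null replicates (20 × 10). The Wald test with a normal reference is
mildly anti-conservative in small samples; with 10 subjects the empirical
size rises to ≈8–11%, which is why calibration is quoted at 20 subjects.
Small-sample df corrections (Kenward-Roger) are out of scope.

## Synthetic phantom

The phantom emulates the *structure* of a 20-patient IGRT study — not CT
physics. Defaults: 64×64×40 voxels at 2×2×3 mm; soft tissue ≈40 HU, bladder
interior ≈10, rectal content ≈−80, bone ≈700, air −1000; Gaussian noise
σ = 12 HU; 2 mm edge smoothing; a smooth random soft-tissue texture
(amplitude 25 HU) that deforms with the anatomy. Rigid structures carry
deliberate cranio-caudal variation (bulging bone cylinders, tapered body
outline, undulating sacrum) so all six rigid degrees of freedom are
observable. The bladder is an ellipsoid (semi-axes 20/17/15 mm), the rectum
a curved tube (radius 8 mm) running cranio-caudally.

**Filling deformation.** Per fraction, each organ is radially rescaled about
its own normalized coordinate: scale s = fill^(1/3) for the ellipsoid
(volume scales by the filling factor exactly) and s = fill^(1/2) in-plane
for the tube, blended C¹-smoothly to identity at 1.8× the organ radius.
Filling factors are log-normal (median 1, σ_log 0.25 bladder / 0.15 rectum
— chosen to produce the clinically described spread from "no filling
instructions", including occasional ≥50% swings; an `extreme_fill` preset
widens them). The map is analytically invertible for these magnitudes
(monotone radial profile, solved by bisection), so each fraction stores its
exact pull-back deformation and the true fraction masks are the planning
masks warped by it (linear interpolation, 0.5 threshold). Bone displacement
under the blend is below 1e-3 voxel at the centroid.

**Setup error** is a small rigid transform (σ = 2 mm / 0.8°, clipped at
8 mm / 3°). **Appearance**: CTOR fractions re-render the noise-free anatomy
with fresh noise; CBCT applies a smooth multiplicative bias field on
attenuation (HU + 1000), then gain 0.8 and offset −30 HU, then noise
σ = 25 HU. These CBCT numbers are stated assumptions (no quantitative
figures were available), chosen so that bladder/soft-tissue contrast
(30 HU × 0.8 = 24) sits at the noise floor — the regime in which purely
intensity-driven registration degrades and organ shadowing pays off.
Content leaving the volume during warping is edge-replicated rather than
zero-filled, so no artificial air slabs appear at volume faces.

**Study layout.** Default 23 fractions per patient; 10 + 10 patients give
460 fraction images, matching the ~453-fraction scale of the emulated
study. Within each modality group, half the patients carry manual contours
daily, the rest on fractions 1–5 and every 5th thereafter.

**What passing on the phantom does and does not show.** The phantom's
deformations are smooth, analytic and moderate; its intensities are
piecewise-constant tissues plus Gaussian noise. Success here demonstrates
the pipeline's internal correctness (geometry, conventions, optimization,
statistics) and the *mechanisms* behind the algorithm orderings — it does
not certify accuracy on clinical images, whose artifacts (scatter, beam
hardening, streaks), sliding interfaces and irregular organ shapes are
deliberately out of scope.

## Problem sizes used in tests and acceptance

Registration checks run on the 64×64×40 default phantom; study-scale
comparisons (4 CBCT patients × 6 fractions) use a two-level pyramid
(32 → 16 mm control points, stopping at half resolution), which preserves
the algorithm orderings at a fraction of the cost of the full three-level
pyramid used for single-pair ground-truth recovery. Mixed-model calibration
uses 200 recovery replicates (20 × 23) and 1000 null replicates (20 × 10).
These sizes are the package's own defaults for its validation experiments.

## Known limitations

* Axis-aligned volumes only; no DICOM, no oblique or 4D data.
* Mono-modal similarity (SSD/NCC); mutual information is not implemented,
  so cross-modality registration relies on the intensity normalization.
* The free-form model has no diffeomorphic guarantee; for large fields the
  interpolate-and-threshold propagation may create topology changes.
* Wald inference with a normal reference; no small-sample df correction or
  multiple-testing adjustment.
* The phantom's rectum is a tube without flexure-level curvature changes,
  and no prostate/target structure is modelled.
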