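# Methods

## Problem

After radical prostatectomy, whole-mount histology sections carry the
pathologist's ground truth about where the tumor actually was, while the
pre-surgical PET/MRI carries what imaging claimed. Comparing the two
quantitatively requires putting a stack of deformed, shrunken, individually
rotated 2D sections and several 3D in vivo volumes into one coordinate
frame. `historeg` implements a five-step bridge through an ex vivo MRI of
the fixed specimen, which shares its deformation state with the sections
and its modality with the in vivo scan:

1. each digitized section is registered to its ex vivo MRI slice with a
   closed-form similarity (rigid + uniform scale) fit of paired fiducial
   landmarks, then embedded into the ex vivo 3D grid;
2. the in vivo T2w volume is registered to the ex vivo T2w volume with an
   automatic rigid + cubic-BSpline free-form deformation driven by mutual
   information (the two ex vivo contrasts share one grid, so no transform
   is needed between them);
3. the step-2 transform carries the first tracer's PET volume (intrinsically
   aligned with the simultaneously acquired in vivo T2w) into ex vivo space;
4. the second tracer session's water MRAC volume is registered to the first
   session's MRAC the same way (with a landmark-affine rescue path);
5. steps 4 and 2 composed carry the second tracer's PET across. The same
   chains move the PET lesion segmentations with nearest-neighbour
   interpolation.

Everything ends on the ex vivo grid; validation uses target registration
error (TRE) on held-out points and per-slice DICE overlap between the
co-registered histology lesion annotation and the PET lesion segmentations.

## Coordinate and transform conventions

World coordinates are LPS millimetres; voxel indices are 0-based and refer
to voxel centers. Every stored transform is a *pull-back*: it maps
reference-space world points into moving-space world points, which is the
direction resampling needs and avoids inverting free-form fields. Chains
are `CompositeTransform`s evaluated pointwise child by child; because a
chain is a function on points, any output volume is produced by a single
resampling pass (one interpolation of the original voxels) even when the
chain contains nonlinear members. The test-suite still verifies the
affine-chain equivalence of single-pass and collapsed-matrix resampling and
measures the blur a sequential double resampling would have introduced.

The similarity estimator is the classical closed-form Procrustes/Umeyama
solution: centroid alignment, SVD of the cross-covariance with reflection
correction, uniform scale from the variance ratio. It is exact (no
iterative optimizer), returns the fiducial residual RMS, and degenerates
loudly on collinear configurations.

The BSpline free-form deformation stores displacement vectors on a coarse
axis-aligned control lattice and interpolates them with tensor-product
cubic B-splines; coefficients outside the lattice are zero, so a zero
lattice is exactly the identity and displacements decay smoothly to zero at
the edge. The fully supported interior is evaluated by scipy's C spline
evaluator on the coefficient array (no prefilter); lattice-edge points go
through an explicit zero-padded basis sum, and the two paths agree to
machine precision where both apply.

## Registration

Mutual information is computed on a 32x32 joint histogram of intensities
sampled at every fixed voxel whose mapped position lands inside the moving
support, with per-image linear rescaling to the bin range by robust
0.5/99.5-percentile min/max, in nats. One constant image gives MI = 0; two
constant images warn and return 0.

The rigid and BSpline stages are optimized with SimpleITK's registration
framework (Mattes mutual information). Metric sampling uses *all* voxels —
no stochastic sampling — so registration is bit-deterministic across runs;
the determinism is asserted in tests. Defaults: rigid on a 4/2 shrink
pyramid (Gaussian smoothing 2/1 mm, regular-step gradient descent, scales
from physical shift, 60 iterations); BSpline at shrink 3 with LBFGSB,
25 iterations, 10 mm isotropic control spacing for the prostate-scale
fixation deformation. Step 4 defaults to a doubled control spacing (20 mm)
because the inter-session offset is near-rigid. These pyramid/iteration
choices were made to reach the phantom's TRE noise floor (see below) at
desk-scale runtimes on the 0.6 mm ex vivo grid; all of them are plain
fields on `RegistrationSettings`. A finer final level buys nothing here
because the MI optimum localizes well below one voxel on these images.

A BSpline refinement is accepted only if it does not decrease the package's
own MI relative to its initialization; otherwise the initialization is
returned with a warning flag. When paired fiducials are supplied,
`register_deformable` additionally checks the fitted transform's median
landmark residual and replaces the automatic result with the closed-form
landmark affine when it exceeds 3 mm (configurable) — the programmatic
version of a manual rescue registration. The pipeline itself never feeds
validation landmarks into this path; TRE points stay strictly held out.

## The phantom

The synthetic study generates, from one seed, everything the pipeline
consumes plus the ground truth the real study cannot have. It emulates the
physical workflow, not MR/PET physics:

* **Anatomy** — an ellipsoidal gland (semi-axes 22/18/20 mm) with a
  transition-zone subregion, a spherical focal lesion (default radius 7 mm,
  i.e. a 14 mm index lesion), smooth intensity bias, piecewise-constant zone
  contrasts that invert between T1w and T2w, and 2% Gaussian noise. Enough
  structure for mutual information; no claim of realism beyond that.
* **Fixation/resection** — the ground-truth specimen transform composes a
  uniform shrink (scale 0.95), a small rigid repositioning (<=2 mm,
  <=3 deg), and a smooth random BSpline field (12 mm lattice, displacements
  ~N(0, 1 mm) clipped at the 2 mm amplitude). It is stored directly in the
  pull-back direction (ex vivo -> in vivo), so generated images sample the
  in vivo anatomy function exactly — no inverse fields and no double
  interpolation anywhere in the generator.
* **Fiducials** — three U-shaped quadratic Bezier strands whose two
  endpoints sit near the basal face; every transverse cutting plane is
  crossed twice, giving six labelled fiducial points per section. Tops,
  radii, spans and bends are randomized so the crossing pattern changes
  shape (not just scale) from plane to plane. Strands render hyperintense
  in T1w (gadolinium-infused thread) and as small holes in histology.
* **Sectioning** — 3 mm trims at apex and base, then complete 3 mm slabs
  (a 40 mm specimen yields 11 body sections). Section planes snap onto
  ex vivo voxel centers (3 mm is an exact multiple of the 0.6 mm grid), and
  each section gets an in-plane rigid jitter (<=5 deg, <=2 mm) before being
  rendered at 512x512 / 0.1 mm. The scene is smooth at that scale, so it is
  evaluated on a 0.2 mm lattice and bilinearly refined.
* **PET** — uptake (gland 1, lesion ~6) blurred with the 4.5 mm FWHM
  Gaussian PSF on a 2 mm grid. The PSMA session sits in a frame offset from
  the RM2/in vivo frame by a small rigid transform (<=1 mm, <=1 deg).
  Lesion segmentations are majority-inside rasterizations of the true
  lesion (3^3 subsamples per voxel); the `discordant_psma` option mirrors
  the PSMA segmentation across the midsagittal plane, emulating a
  false-positive uptake in the contralateral lobe.
* **Validation truth** — per section, the six fiducial crossings and eight
  well-spread intra-gland target points are stored in histology, ex vivo
  and in vivo coordinates, both exact and with isotropic localization noise
  (sigma = 0.3 mm) added independently per space. Registration only ever
  sees the noisy fiducials; TRE only ever uses the noisy targets.

All randomness flows from the seed through named substreams (anatomy /
deformation / jitter / noise / landmarks), so subsystems can be varied in
isolation and the same seed is bit-reproducible.

### What the phantom does not capture

Real histology has stain texture, tears, folds and within-section warps;
real fixation shrinkage is tissue-dependent and not a global similarity;
PET has scatter, attenuation-correction artifacts and reader variability in
lesion delineation; fiducial holes must be found by eye. Passing the
phantom therefore demonstrates the pipeline's geometric correctness and its
behaviour under the modelled deformation/noise budget — not clinical-grade
accuracy on patient data.

## Validation metrics

TRE is the Euclidean distance, in mm, between a mapped held-out point and
its annotated counterpart (`||T(P1) - P0||`), eight points per section,
reported as median and IQR per registration pair. With a perfect transform
the noise floor is the distance between two independent isotropic sigma =
0.3 mm localization errors: median ~0.50 mm in-plane (2D chi) and ~0.65 mm
in 3D. The phantom benchmarks sit close to these floors (pooled over ten
phantoms: ~0.78 mm step 1, ~0.84 mm step 2, ~0.98 mm full chain — the
numbers `scripts/acceptance.py` recomputes), which is what keeps them below
the 1.15 / 1.37 / 1.59 mm reference medians.

Per-slice DICE is computed in 2D on the common ex vivo grid at each
section's axial index. The median uses the midpoint rule for even counts
and the range is min-max, both rounded to two decimals for reporting. A 2 mm
PET grid carried onto a 0.6 mm grid by nearest neighbour has a staircase
ceiling around DICE ~0.9 for a 14 mm lesion, and grazing cross-sections a
couple of mm across cannot be represented at all — overlap acceptance is
therefore evaluated on cross-sections of at least 10 mm equivalent
diameter. Two empty masks score 0 with a warning (no region to compare).

Step comparison: Kruskal-Wallis omnibus (tie-corrected, chi-square df=2)
across the three pooled TRE groups, then pairwise Wilcoxon signed-rank
tests on matched points (exact null for n <= 25 without ties, tie-corrected
normal approximation otherwise; zero differences dropped, Wilcoxon's
original treatment) with Benjamini-Hochberg adjustment over the three
pairwise p values; significance at adjusted p < 0.05. The omnibus test's
null calibration is property-tested (empirical size at 0.05 within
[0.03, 0.08] over 500 simulated null triples).

## Numerical choices and edge cases

* Out-of-support resampling fills with 0 (MRI/PET background).
* Degenerate landmark configurations (collinear within 1e-9 of the spread)
  and singular affine matrices are rejected, not silently regularized.
* Slice correspondence: the manifest's per-section ex vivo index hint is
  authoritative; the residual-based search is a fallback. Under the 0.3 mm
  landmark noise the similarity fit can absorb much of the shape difference
  between *adjacent* planes, so an unrestricted search is only guaranteed
  with noise-free fiducials (where the true plane has exactly zero
  residual); with noise it is reliable within the hint window.
* Ties in the slice search break to the lowest index; registration has no
  stochastic component, so reruns are bit-identical.
* `compose` collapses affine pairs into one affine and never flattens
  nonlinear members.

## Benchmark problem sizes

The standard benchmark (also what `scripts/acceptance.py` runs) uses ten
phantoms at the default 0.6 mm ex vivo / 1.0 mm in vivo / 2 mm PET grids —
about 90x77x84 ex vivo voxels — with the registration defaults above;
roughly half a minute per phantom end to end. The paper-resolution 0.3 mm
ex vivo grid is selectable (`exvivo_voxel_mm=0.3`) and multiplies the
registration cost by ~8 without changing the contracts.

## Known limitations

* Histology-to-slice registration is similarity-only by design (step 1);
  within-section nonrigid distortion is out of scope.
* The MI implementation quantizes with hard bin edges (no Parzen window);
  it is the reasoning/acceptance metric, while the optimizer uses Mattes MI.
* BSpline registration is not guaranteed diffeomorphic; at the default
  amplitudes folding does not occur, but extreme settings can fold.
* The affine rescue path needs user-supplied paired landmarks; without
  them, a failed deformable stage falls back to its rigid initialization
  only.
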