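# Methods

This note records the modelling choices behind `otoradiomics`: what each
stage computes, the knobs that matter, what the synthetic cohorts do and do
not emulate, and the numerical conventions that make results reproducible.

## Problem setting

The package implements a diagnostic classification workflow for Menière's
disease from conventional T2-weighted MRI of the inner ear. The unit of
analysis is an *ear*: a 3D MR volume plus a binary segmentation of the
labyrinth (cochlea, vestibule, semicircular canals). The positive class is
`patient` (MD ear), the negative class `control`. Data come from multiple
centers with heterogeneous scanners, so the pipeline has to be robust to
per-center intensity scaling and anisotropic voxel spacing; preprocessing
exists precisely to absorb those.

## Synthetic cohorts

No suitable public dataset pairs inner-ear T2 volumes with labyrinth masks
and MD labels, so the package generates its own phantoms.

**Geometry.** A labyrinth-like solid: a vestibule ellipsoid (semi-axes
3.2 × 2.4 × 2.0 mm) plus three mutually orthogonal semicircular-canal torus
arcs (ring radius 5 mm, tube radius 0.9 mm, 150° arcs). The three arc
planes are offset ±1.2 mm from the vestibule center and the arc ends are
trimmed 15° away from the ring crossings, which makes the four solids
pairwise disjoint; the analytic ROI volume is then exactly the sum of an
ellipsoid and three partial tori (≈ 164 mm³, close to a real labyrinth's
order of magnitude). Masks are voxelized by the voxel-center rule on a 48³
grid.

**Intensities.** T2 fluid is bright: ROI mean 300, background 100
(arbitrary units), additive Gaussian noise of SD 20 with a ~0.4 mm
correlation length (white noise smoothed by a Gaussian kernel and rescaled
to unit SD; a Rician magnitude model is available as a flag). Each of the
four centers A–D applies an affine intensity transform (scales 0.8–1.25,
offsets −25…+40) and acquires on its own, partly anisotropic grid
(0.4–0.8 mm).

**Class effect.** Patients differ from controls by (i) a focal
hypointensity — a saccule-scale sub-region covering a fixed fraction of the
ROI (default 15 %, selected as the ROI quantile of an anisotropic distance
field so the fraction is exact) whose intensity drops by `delta` × noise SD
(default 3); (ii) an analytic dilation of all radii (default 0.2 mm,
sub-voxel capable); and (iii) a shift of the noise correlation length
(default +0.2 mm), which perturbs texture. Setting all three to zero makes
the classes identically distributed, giving an exact null. The defaults
constitute the "strong effect" condition used by the end-to-end checks: a
lesion three times the noise SD over 15 % of the ROI should be trivially
learnable, and the pipeline is required to recover it at ≥ 90 % held-out
accuracy, while the null must sit inside the 95 % binomial band around
chance.

**What the phantoms do not emulate:** cochlear spiral anatomy, partial
voluming from true MR acquisition (k-space truncation, bias fields),
segmentation error, age/laterality structure. Passing tests therefore show
the *pipeline* is correct and sensitive, not that real MD ears are
separable — that question needs the clinical data.

Determinism: every ear's noise is drawn from a seed derived via
`SeedSequence([master_seed, ear_index])`, so cohorts are bit-reproducible
and geometry (which is noise-free) is seed-independent.

## Preprocessing

1. **Resampling** to isotropic 0.5 mm with cubic B-spline interpolation
   (SimpleITK); masks are interpolated as floats and re-binarized at 0.5.
   The output grid keeps the input origin, and its size is chosen so every
   output voxel center lies inside the input sampling domain (no
   padding-filled edge voxels); the world extent is preserved to within one
   voxel.
2. **Z-score normalization** over the full volume (population SD). The ROI
   occupies a tiny, center-dependent fraction of the volume, so full-volume
   statistics are dominated by background and the transform mainly removes
   the per-center affine intensity differences. A `scope="roi"` switch
   restricts statistics to the mask.
3. **Discretization** with fixed bin width 0.5 in normalized units,
   anchored at the ROI minimum: `label(x) = floor((x − min)/0.5) + 1`,
   `Ng = floor((max − min)/0.5) + 1`. Anchoring at the minimum makes labels
   invariant to intensity offsets.

## The 812-feature roster

The roster is fixed and ordered: 20 shape features plus, for each of nine
image versions (original + eight stationary wavelet sub-bands), 18
first-order, 26 GLCM, 16 GLRLM, 16 GLSZM, 7 GLDM and 5 NGTDM features —
20 + 9 × 88 = 812. Names follow `<ImageType>_<Group>_<Name>`
(`orig_Stats_min`, `wavelet-HHL_GLCM_contrast`, …). The classic texture
literature contains a few algebraically redundant GLCM descriptors (e.g.
sum average = 2 × joint average for symmetric matrices); they are kept
because historical rosters of this size include them, and the total and
group sizes are part of the package contract. A JSON manifest of the
roster is exportable for provenance.

Conventions that are deliberate choices (the field has no single standard):

- **Wavelet**: single-level stationary (undecimated) 3D transform,
  Coiflet-1. Undecimated sub-bands stay on the input grid so the original
  mask applies unchanged. Odd axes are symmetrically padded to even length
  and cropped back. Each sub-band is *independently re-discretized* with
  bin width 0.5 over the ROI before histogram/texture features.
- **GLCM**: symmetric matrices at Chebyshev distance 1, one per each of the
  13 unique 3D directions; features are averaged over directions (not
  computed on a merged matrix).
- **GLRLM**: runs along the same 13 directions, averaged; the
  length-weighted total per direction equals the ROI voxel count by
  construction.
- **GLSZM**: zones are 26-connected components of equal gray level.
- **GLDM**: distance 1, equality (α = 0); the dependence index is 1 (the
  voxel itself) plus the number of equal-valued in-ROI 26-neighbors.
- **NGTDM**: 26-neighborhood mean, voxels with no in-ROI neighbor excluded.
- **Degenerate flat ROIs** (Ng = 1, common on detail sub-bands of constant
  regions) take limit values instead of erroring: entropies 0, energies 1,
  GLCM correlation and MCC 1, NGTDM coarseness capped at 10⁶.
- **First-order**: percentiles by linear interpolation; population
  variance; Pearson (non-excess) kurtosis; skewness/kurtosis defined as 0
  for zero-variance ROIs; entropy/uniformity on the discretized histogram.
- **Shape**: computed on the mask only, in mm. Surface area and mesh volume
  come from a marching-cubes isosurface of the mask mildly smoothed with a
  Gaussian (σ = 0.7 voxels) — binary marching cubes overestimates a digital
  ball's area by ~9 % through staircasing, and the smoothed surface brings
  sphericity of a radius-10 ball to 0.987 with volume within ~2.4 %.
  Single-voxel-thin structures, where smoothing would erase the surface,
  fall back to the binary isosurface. Because marching cubes resolves
  ambiguous cells orientation-dependently, on isotropic grids the
  volume/area estimates are averaged over all 24 axis-aligned orientations,
  making them *exactly* invariant under 90° grid rotations. Axis lengths
  use 4√λ of the voxel-coordinate covariance eigenvalues; the maximum 3D
  diameter is the largest pairwise distance over convex-hull vertices;
  bounding-box extents are reported sorted (max/mid/min) so they too are
  rotation-invariant.
- Extraction crops to the ROI bounding box plus an 8-voxel margin before
  filtering, which bounds cost and makes all features exactly invariant
  under whole-voxel translations of interior ROIs.

## Reduction and importance

Features are standardized with training-row means/SDs (near-constant
features, SD < 1e-12, have their SD clamped to 1, effectively zeroing
them). PCA retains k = 10 components (full SVD; sign fixed by making each
component's largest-magnitude loading positive, so fits are deterministic).
Test rows always reuse training standardization — no leakage.

The per-feature contribution score is the mean of |loading| across the 10
retained components, divided by its maximum so scores live in [0, 1]; the
selection threshold is 0.7. This is one concrete realization of
"inverse-PCA mean contribution" importance: with unit-norm loading columns
the raw mean absolute loading has no natural absolute scale, so the cutoff
is made scale-free by max-normalization. On cohorts with a planted
correlated discriminative feature block, that block tops the ranking
(tested); the specific features selected on synthetic phantoms carry no
clinical meaning.

## Classifier

An MLP on the 10 PC scores: one hidden layer of 500 ReLU units, Adam at
learning rate 0.001, up to 1000 full-batch epochs, early stopping with
patience 20 on an internal validation split (10 % of the training rows)
that restores the best-validation weights. scikit-learn's `MLPClassifier`
provides the optimizer; for two classes its single logistic output yields
exactly the softmax class-1 probability, and the decision threshold is 0.5.
Early stopping is always carved from the training partition, never the
external test set: using the test center to time the stop would leak the
evaluation data into training, so the package deliberately keeps the test
set untouched until scoring. Training is deterministic given the seed.

## Evaluation

- **Center-aware split**: the designated external center (default D) goes
  entirely to the test set, which is filled up to `round(0.26 n)` with a
  seeded random draw from the other centers; train and test are disjoint.
  On the study-shaped 260-ear cohort this yields 192 train / 68 test.
- **10-fold CV**: stratified by class (folds of 26 on 260 ears); when k
  exceeds the smaller class count (e.g. leave-one-out) the plan falls back
  to a plain shuffled partition.
- **Metrics**: textbook ratios of the confusion matrix with patient
  positive; rates in percent, F1/MCC on their natural scales; zero
  denominators yield NaN with a warning rather than a silent 0. AUC is the
  midrank Mann–Whitney statistic. CIs are stratified nonparametric
  bootstrap percentiles (2000 resamples by default); degenerate resamples
  are skipped and counted.
- `reconstruct_matrix_from_rates` inverts printed sensitivity/specificity
  pairs to the nearest integer confusion matrix (ties toward the larger
  count), which lets published summary tables be re-expanded into full
  metric sets exactly.

## Problem sizes and runtime

The end-to-end checks run the full pipeline on study-shaped cohorts of
120 + 140 ears at 48³ generation grids; feature extraction takes ~0.4 s per
ear (~2 min per cohort) on one CPU, and the acceptance script (two cohorts
plus oracles and reruns) completes in a few minutes. These sizes were
chosen to mirror the study cohort while keeping a full reproduction
desk-scale.

## Known limitations

- The phantom is a geometric stand-in; none of its class effects are claims
  about MD biology (the plausible biological correlate — saccular hydrops
  altering low-signal regions — motivates the *focal hypointensity* design,
  nothing more).
- The 812-name roster reproduces the published feature *count* and group
  structure; the original extraction software's exact roster is
  proprietary, so per-feature name-level agreement with it is out of scope.
- The contribution score is one documented formalization of loading-based
  importance; alternative normalizations would reorder scores near the
  cutoff.
- Bootstrap CIs assume exchangeability within class; with 24 external-center
  test ears they are wide, and the package reports them as such.
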