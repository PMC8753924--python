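# Methods

`ctgrain` re-creates, end to end and on synthetic data, a phenotyping
pipeline for grain micro-CT: stacks of 2-D slices are preprocessed,
segmented voxel-by-voxel into five classes with a trainable random forest,
summarized into per-unit volumetric/texture/intensity traits, and analyzed
with a replicated-design mixed model. This note documents the models, the
parameters that matter, and the choices made where the design was open.

## The phantom and what it emulates

Real scans image a foam plate: each well holds the 40 kernels of one
genotype (one *experimental unit*), 21 wells per scan, three scans acting
as replicates. The generator reproduces the statistical structure of such
scans rather than their physics:

* **Kernel anatomy.** A kernel is an ellipsoid (semi-axes in mm). The
  outermost shell of a fixed physical thickness is pericarp; a polar lobe
  embedded in the endosperm (scutellum-like, grown by exact voxel count
  from an off-center seed point) is embryo; the remaining endosperm is
  split into a peripheral hard (vitreous) shell and a central soft
  (floury) core, again by exact count on the normalized radius. Because
  every region is constructed by sorting voxels, the ground-truth label
  counts are exact by construction.
* **Graded boundaries.** Class-mean intensities are blended with a
  Gaussian of sigma 0.6 voxels (a ~2-voxel transition band) before
  per-class speckle is added; tissue interfaces in real kernel scans are
  gradations, not steps, and the classifier must be exercised on that
  difficulty. Voids are the exception: they are carved *after* blending
  with crisp edges, because cracks and hollow cavities are fractures, not
  developmental gradients. Void voxels carry the background label, so they
  are excluded from every component count.
* **Radiometry.** Default 8-bit class means are background 8, soft
  endosperm 120, hard endosperm 175, embryo 195, pericarp 215 with
  per-class speckle scales of 2-10: embryo overlaps hard endosperm and
  sits near pericarp, mirroring the confusion structure of real kernel
  scans (hard endosperm mistaken for embryo and vice versa). No published
  per-tissue density calibration exists, so these are free parameters. A
  `separated` variant (soft 120 / hard 175 / embryo 205 / pericarp 235,
  speckle 3 everywhere) keeps every pairwise mean gap at least four times
  the combined within-class scale; it is the configuration under which
  recovery accuracy is validated, the default being deliberately harder.
* **Scan-level degradations.** Per-scan additive brightness offsets
  (default draw +-8), an optional radial attenuation multiplier across the
  plate, and additive Gaussian noise (default sd 5) are applied to
  intensities only, after ground truth is extracted.
* **Within-genotype variability.** Each kernel's size is scaled by a
  downward half-normal factor (cv 0.035, bounded so kernels never outgrow
  their packing cell) and its hard/embryo fractions are perturbed
  (sd 0.025 / 0.01). Both jitters are calibrated to roughly 10%
  within-line coefficients of variation on kernel volume and texture
  ratio. Without them every scan would measure geometrically identical
  units and the entry-mean repeatability would be exactly 1 by
  construction.
* **Genotype panel.** The default 19-genotype panel varies size (+-11%),
  pericarp thickness (0.27-0.33 mm), embryo fraction (0.10-0.15) and
  hard-endosperm share (0.50-0.80, i.e. texture ratios ~1-4, the range
  real sorghum panels span); one genotype is waxy (endosperm means lowered
  by 6, the "slightly less dense" mutant), one is void-prone
  (30% of kernels carry an internal cavity). The waxy and void variants
  need no special handling anywhere downstream — the pipeline treats them
  identically, which is itself part of what the phantom demonstrates.
* **Placement.** Kernels occupy a jittered disjoint slot lattice inside
  each well. At the scanned density (40 kernels per well at desk-scale
  resolution) sequential rejection sampling cannot pack the well, so the
  lattice guarantees feasibility; an explicit error names the constraint
  when a well cannot hold the request.
* **Determinism.** Every random draw descends from one root seed through
  `numpy.random.SeedSequence` keyed by (seed, scan, well row, well column,
  kernel index, stream), so generation is bit-reproducible and individual
  kernels are reproducible in isolation.

### Desk scale

The deliverable runs on one CPU, so the default configuration is a scaled
image: 0.25 mm voxels (vs 20.2 µm in a real scanner) with 64^3-voxel
wells. At that scale a kernel spans ~1,000 voxels and the pericarp must be
thickened to stay resolvable (~1.2 voxels), so phantom tissue fractions
are *not* real sorghum composition (the phantom pericarp is ~40% of kernel
volume instead of ~9%). All recovery statements are against the phantom's
own exact ground truth, which is the quantity a phantom can validate. The
recovery-validation study additionally uses geometrically exact
(jitter-free) kernels, because per-kernel fraction jitter at this
resolution creates sub-voxel soft cores whose misclassification measures
discretization, not the classifier.

## Preprocessing

8-bit conversion is a linear min-max rescale with round-half-up (constant
stacks map to zero). Contrast enhancement clips `saturated_fraction`
(default 0.3%, split equally between tails — the conventional semantics of
stack-histogram contrast stretching) at quantiles of the pooled
whole-stack histogram, never per slice, then stretches linearly to
[0, 255]. The transform is monotone and invariant to constant offsets;
order is fixed as 8-bit conversion first, then enhancement.

## Feature bank

Per voxel: raw intensity plus, at each sigma of the ladder {1, 2, 4, 8}
(the stated range is min 1 / max 8; power-of-two rungs follow the
referenced tooling's convention), the Gaussian local mean, the Gaussian
local variance (second moment minus squared mean, clipped at zero), and
the three signed-sorted eigenvalues of the Gaussian-scale Hessian —
21 channels with the default ladder. All filters are true 3-D operators
with reflect borders. Gaussian kernels are truncated at 4 sigma, so a tile
padded with a halo of `ceil(4 * sigma_max)` voxels reproduces the
whole-volume computation exactly; this is what makes tiled prediction
bit-identical to whole-volume prediction.

## Segmentation

* **Training set.** On phantoms, manual annotation is replaced by sampling
  ground-truth labels on ten consecutive slices per scan (a CSV reader
  ingests real voxel annotations). The per-scan budget is apportioned
  exactly (largest remainder) across classes — equal shares by default,
  configurable — and every genotype present on the annotation slices is
  guaranteed a sample by swapping, keeping per-scan totals within one of
  `n_samples / n_scans`. The slice window defaults to the center of the
  stack but can be pinned, since an annotator picks slices that show every
  tissue. The reference training-set size is 52,966 voxels.
* **Classifier.** A random forest of 200 trees with 2 candidate features
  per split (scikit-learn), single-threaded for determinism. Prediction is
  the argmax of vote fractions with ties broken toward the lower class
  index (background < pericarp < embryo < soft < hard) — an arbitrary but
  fixed rule that makes output independent of tree evaluation order.
* **Evaluation.** Ten iterations of stratified fivefold cross-validation;
  percent correct is averaged over iterations and RMSE is the root mean
  squared difference between one-hot truth and predicted class
  probabilities (the probability-error convention of the reference
  tooling). Folds fall back to unstratified with a warning when a class
  has fewer samples than folds.
* **Tiled prediction.** One tile per well (the scanned layout allocates
  one genotype per tile) padded by the feature halo; tiles at the volume
  edge see the true boundary, so tiled output equals whole-volume output
  voxel for voxel. A halo below the feature support is rejected.

## Traits

Per experimental unit: component volume = class voxel count x voxel
volume / kernels-per-well, kernel volume = the four-tissue sum (exact on
integer counts), endosperm texture = hard/soft voxel ratio (NaN when soft
is zero, never infinity), and endosperm intensity = the mean of the unit's
voxels within [70, 248] on the preprocessed stack — thresholds inclusive
at both bounds, voxel-pooled across slices and kernels, and computed
without the segmentation (the window itself excludes background and the
brightest embryo/pericarp-level voxels). Units with undefined values
propagate NaN. The voxel edge is cubed for mm^3, the only dimensionally
consistent reading of an isotropic calibration.

## Statistics

Each trait is modeled as

    Y = mu + Genotype + Rep + Col + Row + E,

with Rep the scan and Row/Col the well position. Variance components are
estimated by profile REML written for this package: the likelihood is
profiled over the fixed part and the residual scale and optimized over
bounded variance ratios (L-BFGS-B, three starts). A general mixed-model
library fit through its crossed-random-effects interface proved too
fragile at this design size, converging away from the REML optimum; the
in-package engine is validated against lme4 in the test suite. Components
that land on the zero boundary — the constrained analogue of a negative
estimate — are pruned smallest-first and the model refit, with the order
logged.

With genotype random the fit yields EBLUPs (Henderson's equations),
R^2 = 1 - sigma2_e / var(Y), and entry-mean repeatability
R = sigma2_g / (sigma2_g + sigma2_e / r) with r the number of scans.
With genotype fixed it yields GLS BLUEs (equal to genotype means in
balanced designs). The Tukey-Kramer HSD uses the studentized range with
residual df from the all-factors-fixed analogue of the final model and the
unequal-replication standard error for the check entry's extra wells; a
compact letter display is built by insert-and-absorb. Residual normality
is checked by Anderson-Darling at alpha 0.05 with a log10 refit for
non-normal, strictly positive traits. Pearson correlations among
genotype-level estimates (and optional external reference columns such as
single-kernel hardness or visual texture scores) are flagged at p < 0.01.

Repeated REML on the replicated design carries an intrinsic downward
median bias of a few percent in sigma2_g (the estimator's distribution is
right-skewed), visible in Monte-Carlo recovery; both components stay
within 10% median bias at the default design size.

## Problem sizes used for validation

The recovery-validation study is 3 scans of 2x3 wells (6 genotypes
including the waxy, void-prone and repeated-check entries), 40 kernels per
64^3 well, separated radiometry, noise sd 4, with a 52,966-voxel training
set; cross-validation runs on a stratified 8,000-voxel subset to keep the
50 forest refits tractable. The statistics stage is exercised on the full
21-well, 19-genotype design measured from exact labels, and on 200
Monte-Carlo replicates of the design model itself. End-to-end
reproducibility is checked by running the whole pipeline twice from one
config on a 4-genotype miniature.

## Known limitations

* The phantom models image statistics, not physics: no beam hardening,
  ring artifacts, partial-volume projection or reconstruction noise
  correlation. Passing tests show the pipeline recovers what this phantom
  contains; they do not certify accuracy on scanner data.
* Desk-scale tissue fractions are unrealistic (thick pericarp), and the
  per-unit recovery bound is validated under the separated radiometry —
  under the default overlapping radiometry, embryo/hard confusion is
  intentionally present and component recovery degrades accordingly.
* Repeatability on the phantom reflects only kernel-sampling and
  classifier error; real scans add positioning, moisture and instrument
  drift, so phantom R values are optimistic.
* One genotype per well is assumed (no per-kernel instance segmentation),
  and wells must tile the scan exactly.
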