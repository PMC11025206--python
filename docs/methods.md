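# Methods

## Overview

`plexus` implements a choroid-plexus (CP) volumetry pipeline for structural
MRI together with the cohort-level statistics used to relate CP volume to
clinical disability and blood–CSF-barrier permeability in ALS. Because the
motivating cohort's raw images and clinical records are not publicly
deposited, the package ships a synthetic front end — brain phantoms with
known CP ground truth and cohort simulators calibrated to the published
group summaries — so every stage is testable end to end.

## Segmentation model

The pipeline assumes a T1-weighted volume in which the ventricular system
has been labelled by an aseg-style anatomical segmentation (FreeSurfer
codes 4/43 lateral ventricle, 5/44 inferior lateral ventricle, 31/63
choroid plexus). On T1 images CSF is dark, the ventricle wall is of
intermediate intensity (partial volume between CSF and parenchyma), and
the CP is bright. The stages are:

1. **Initial mask** — the union of the six ventricular-system labels.
2. **Stage-1 clustering** — a 2-component univariate Gaussian mixture on
   the initial-mask intensities; voxels hard-assigned to the higher-mean
   component form the wall + CP class, the rest are CSF.
3. **SUSAN smoothing** (sigma = 1 mm, kernel truncated at 3 sigma)
   restricted to the wall + CP class. Weights combine a spatial Gaussian
   with an intensity-similarity Gaussian, so noise is averaged within
   tissue classes while the wall/CP edge is preserved.
4. **Stage-2 clustering** — a 3-component mixture on the smoothed values;
   the highest-mean component is the CP.
5. Optional reproducible **manual edits** (explicit add/remove voxel
   lists standing in for expert correction), then **volumetry** as voxel
   count x voxel volume (mm^3).

Masks are nested by construction (final CP ⊆ stage-1 high ⊆ initial); the
pipeline clamps edited masks to the stage-1 domain so the invariant holds
for any edit list.

### Mixture fitting

The mixture fitter is univariate EM with two modes. The default, MAP-EM,
places a Dirichlet(1 + 1e-3) prior on the weights and a
Normal-Inverse-Gamma prior centred on the sample moments (kappa0 = 1e-3,
a0 = 1e-3, b0 = a0 x sample variance) on each mean/variance pair. The
priors are weak enough that estimates track maximum likelihood, while all
M-steps stay closed-form (the exact joint mode of the conjugate
posterior), which guarantees a non-decreasing objective — asserted per
iteration in the tests at 1e-8 relative tolerance. Plain ML-EM is
available by config.

Numerical choices:

- **Initialisation**: deterministic quantile init (component means at the
  (2i-1)/2k sample quantiles); random init with an explicit seed optional.
- **Convergence**: relative objective change < 1e-6, max 500 iterations.
- **Variance floor**: 1e-6 x sample variance; falling below it (or a
  zero-variance sample) raises an explicit fit error rather than silently
  regularising.
- **Ties**: hard assignment prefers the higher-mean component, then the
  lower index; "highest-mean component" selection breaks mean ties toward
  the larger variance, then the lower index. Component relabelling
  therefore never changes a segmentation.

### SUSAN parameters

The brightness threshold defaults to 0.1 x (P95 − P5) of the intensities
inside the smoothing domain — roughly a tenth of the local tissue
contrast, small enough to keep the ~40-unit wall/CP edge intact. A voxel
with no masked neighbour inside the kernel falls back to its own value
(identity), a deliberate divergence from FSL's median fallback: inside a
masked domain the median of an empty neighbour set is ill-defined, and
identity keeps the operator a convex combination of masked inputs.
Distances are physical (mm), so anisotropic voxels are supported.

## Phantoms

A phantom places two ellipsoidal lateral ventricles (default semiaxes
9 x 21 x 11 mm) plus small inferior horns in a 96^3 1 mm grid, surrounds
each with a wall rim (2 mm), and floats spherical CP blobs (3 per
ventricle, radius ~3 mm) in the ventricular CSF. Default intensities are
background 100, CSF 30, wall 70, CP 110 (arbitrary units) with additive
Gaussian noise (SD 5). A light Gaussian blur (sigma 0.3 mm) emulates
partial-volume mixing at interfaces; without it a noiseless phantom would
be piecewise-constant and mixture fits on it degenerate. Blob layout is
drawn from a dedicated `geometry_seed`, so the main `seed` changes only
the noise field — phantoms with the same geometry are exact replicates up
to noise.

What the phantom does **not** emulate: bias fields, k-space artefacts,
anatomical variability of ventricle shape, CP attachment to the ventricle
wall, and FreeSurfer label errors. Recovery results on phantoms therefore
demonstrate correctness of the clustering/smoothing logic under the
stated intensity model, not clinical accuracy on real scans — where
manual review (here: the edit-list mechanism) remains part of the
procedure.

## Cohort simulation

Per group (defaults: 12 genetic ALS, 143 sporadic ALS, 105 HC), CP
volume, age, sex, education, duration, HARS and HDRS are drawn from the
published group means/SDs (truncated normals where physiology demands
positivity). TIV is Normal(1.45e6, 1.5e5) mm^3 truncated positive — a
plausible adult range; the published study uses TIV only as a covariate
and reports no distribution. Sex has no simulated effect on CP volume (no
published effect size).

ALSFRS-R (pooled ALS: 40.3 ± 3.7, bounded [0, 48]) and Qalb (5.9 ± 2.8
mg/g on the 115-patient albumin subsample, floored at 0.2) are generated
from a latent linear model on z, the standardised residual of CP volume
after regressing on age, sex and TIV within the analysed sample:

    y = mu + sd * ( r_lat * z + sqrt(1 - r_lat^2) * eps )

Three refinements make the recovered partial correlations unbiased at the
targets (−0.226 for ALSFRS-R, 0.479 for Qalb):

1. `r_lat` is solved (Brent root-finding on truncated-normal moments via
   Gauss–Hermite quadrature) so the *post-truncation* population
   correlation equals the target;
2. `eps` is orthogonalised in-sample against the covariate design, so
   residualising y during analysis cannot shrink the noise and inflate r;
3. the first-order small-sample attenuation r(1−r^2)/n of a sample
   correlation is compensated analytically.

A 1000-replicate Monte-Carlo check puts the residual bias of both targets
below 0.002. Qalb is decomposed into serum albumin (Normal(45, 3) g/L,
truncated) and CSF albumin = Qalb x serum, so the tabulated quotient is
exactly CSF-Alb/serum-Alb. The Table-2-style per-subgroup ALSFRS-R means
are *not* separately imposed: the pooled latent calibration owns that
variable, since imposing subgroup shifts as well would decalibrate the
pooled partial correlation.

Healthy controls carry no disease variables. The baseline progression
rate column is (48 − ALSFRS-R)/duration per subject; note its cohort mean
is a mean of ratios, not the ratio of the cohort means.

## Statistics

- **Qalb** = CSF albumin (mg/L) / serum albumin (g/L), numerically mg/g.
- **BPR** = (48 − ALSFRS-R) / disease duration (months).
- **Group comparison**: OLS of the outcome on group dummies + age, sex
  (coded F=0/M=1) and TIV; omnibus F from the nested comparison against
  the covariates-only model; all pairwise contrasts tested on the full
  model with Bonferroni FWE correction over the pairwise family (m = 3
  for three groups; Holm by flag). Two-sided p throughout, alpha 0.05.
- **Partial correlation**: residualise both variables on covariates +
  intercept, Pearson r of residuals, p from t = r sqrt(df/(1−r^2)) with
  df = n − 2 − k.
- **Summary-statistic tests**: one-way ANOVA and pooled/Welch t
  reconstructed from printed (n, mean, SD); Pearson chi-square without
  continuity correction. These agree exactly with raw-data tests whenever
  raw data match the summaries, which the tests verify by affine
  reconstruction.
- Missing values are handled complete-case per analysis, matching the
  per-analysis n of the motivating study (e.g. 115 of 155 for Qalb).

Reconstructed worked examples: the printed sex-by-group table gives
chi-square 2.84 exactly; the ALSFRS-R subgroup summaries give |t| = 2.18
against a printed 2.16; the CP-volume summaries give F = 13.09 against a
printed 13.3 — both within rounding of the printed inputs.

## Problem sizes

Default validation sizes were chosen so the whole suite runs comfortably
on a single CPU: 96^3 phantoms (10 noisy seeds for recovery), 200
simulated cohorts for the power surrogate and for partial-r recovery, and
1000 replicates (offline, during development) for the calibration audit.

## Known limitations

- The phantom's intensity model is stylised; no claim is made about
  segmentation accuracy on real T1 scans without manual review.
- "Bayesian GMM" hyperparameters, the SUSAN brightness threshold, and any
  minimum-size filtering are not published for the motivating pipeline;
  the defaults here are documented choices, configurable but not paper
  facts. A connected-component size filter exists but is off by default.
- The simulated covariates are independent of group except where the
  published demographics imply otherwise (age in genetic ALS); the
  simulators reproduce first- and second-order structure, not the full
  joint distribution of a clinical cohort.
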