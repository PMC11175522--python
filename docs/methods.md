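# Methods

This note records the model, the conventions the implementation fixes where
the method leaves room, and what the synthetic generators do and do not
emulate.

## Relative Hounsfield units

Early irreversible ischemia depresses attenuation on CTA source images
(hypo-attenuation tracks depressed cerebral blood flow during contrast
transit). Absolute HU in contrast-enhanced brain varies with bolus timing
and scanner protocol, so each region is normalised by its mirror region:
rHU = mean HU (occluded side) / mean HU (contralateral side). Conventions:

- **HU window [1, 250], inclusive at both ends**, applied identically to
  the ipsilateral and contralateral means. The window drops air/CSF/fat
  (≤ 0 HU) and bone or dense vessel (> 250 HU) voxels that bleed into a
  region mask through registration error.
- The mean is the plain arithmetic mean of stored intensities after NIfTI
  scl_slope/scl_inter scaling; no trimming or winsorising.
- Regions are measured in subject CTA space: atlas masks are resampled
  onto the CTA grid (template→subject transform supplied per patient), the
  CTA itself is never interpolated, so the HU window applies to raw voxels.
- A region with no voxels left after the window raises an explicit
  per-region error rather than returning a silent NaN.

## Geometry and resampling

Masks move between grids by nearest-neighbour sampling through
`mask.affine⁻¹ ∘ transform⁻¹ ∘ reference.affine`, with out-of-bounds
samples set to background (0). Nearest-neighbour keeps masks binary so
overlap arithmetic stays an exact voxel count; out-of-bounds-as-zero is
conservative for overlap fractions. Voxel indices are 0-based; world
coordinates are mm as given by the NIfTI affine. Transform files are plain
4×4 world-mm affines; FSL FLIRT's scaled-voxel `.mat` dialect depends on
image headers and qform flips and is deliberately not parsed.

Atlas validation requires all 20 region masks on one grid, non-empty,
pairwise disjoint **across both hemispheres** (a midline bleed would
corrupt the left/right ratio), and each left/right pair on opposite sides
of the grid's midsagittal plane. The ASPECTS parcellation itself has no
canonical boundaries; the atlas is an input, and the packaged block atlas
exists for testing, not anatomy.

## Infarct ground truth

A region is infarcted when ≥ 30% of its voxels intersect the DWI lesion
mask. The denominator is the region's voxel count *after* resampling to
the DWI grid — the space where the intersection is computed. The boundary
is inclusive and evaluated on the exact rational count ratio
(`Fraction(n_inter, n_region) >= 3/10`), so a lesion covering exactly 30%
of a region is infarcted regardless of float representation. Only the ten
occlusion-side regions are labelled (unilateral LVO); lesion volume is
voxel count × voxel volume / 1000 mL. Missing 3-month mRS is handled
upstream as an explicit imputed-from-discharge flag column, never silently.

## Threshold model

- **Orientation is fixed**: low rHU indicates the positive (infarcted)
  class everywhere; no auto-orientation. AUC is the Mann-Whitney
  probability that a random positive scores lower than a random negative,
  ties counted ½.
- **Youden search.** Candidate thresholds are the midpoints between
  consecutive distinct observed scores plus the two trivial boundaries
  (predict none / predict all); prediction is *strictly* below the
  threshold. J is scored on integer counts (tp·n_neg + tn·n_pos), so exact
  ties stay exact, and ties break toward the smallest threshold. The
  midpoint convention is the standard Youden implementation; published cut
  points from other stacks may differ in the third decimal if they report
  observed values instead of midpoints.
- **Cross-validation** is a single round of k = 10 folds with unstratified
  simple random allocation of patients (not region rows), seed recorded in
  the report. Fold × region metric cells that are undefined because a class
  is absent in the held-out fold are excluded from the mean ± SD aggregate
  and counted, never zero-filled — zero-filling would bias the aggregate
  downward for low-prevalence regions.

## Outcome statistics

- Threshold-based ASPECTS = 10 − (regions with rHU below their cut point).
- Spearman r_S uses average ranks; its 95% CI is a patient-level
  percentile bootstrap (default 2000 replicates). Bootstrap rather than
  Fisher-z because integer ASPECTS scores carry heavy ties that break the
  normal approximation.
- The comparison of two predictors sharing one outcome (automated vs.
  visual ASPECTS against DWI-ASPECTS or infarct volume) is a percentile
  bootstrap for overlapping dependent correlations: resample patients,
  compute Δr per replicate, two-sided p = 2·min(P(Δ>0), P(Δ<0)) with
  zero-replicates split between sides — identical predictors give p = 1
  exactly. Which small-sample adjustment of the published bootstrap family
  to use is not pinned down by the method's citation; the plain percentile
  variant is used, and its type-I error at n = 150 is verified by
  simulation in the acceptance checks.
- DeLong's test uses placement values with midrank ties; the variance of
  the AUC difference comes from the paired placement covariances. When
  that variance is 0 with Δ = 0 (identical scores), p = 1 by convention.
  For functional outcome the risk score is 10 − ASPECTS (fixed
  orientation: lower ASPECTS ⇒ higher risk). The DeLong core takes
  higher-risk-positive scores, the mirror image of the rHU orientation;
  the two are one sign flip apart and their agreement is asserted in the
  tests. The implementation reproduces R pROC's `roc.test` to 10 decimals
  on a frozen instance.
- All p-values are two-sided; all bootstraps take an explicit seed.

## Synthetic generators

**Phantom pairs** place 20 mirror-symmetric disjoint cuboids ("block
atlas") in a 64×64×40 grid at 2 mm isotropic voxels, background 35 HU
(normal parenchymal attenuation on CTA source images) with Gaussian noise
(SD 2 HU by default, optionally mirrored across the midline so symmetric
regions stay exactly symmetric). Ipsilateral hypo-attenuation is planted
as a per-region multiplier on the background; DWI lesions fill the
smallest voxel count reaching at least the requested fraction of a region
(exact rational arithmetic, so a requested 30% truly meets the ≥30% rule).
An optional rigid misregistration (≤ 5° / ≤ 5 mm, keeping nearest-neighbour
resampling sane at phantom resolution) separates template from subject
space and is returned as the correcting transform. The phantom emulates
the *arithmetic* the pipeline performs — ratios, overlaps, resampling —
not CT physics: no beam hardening, streaks, partial-volume gradients, or
realistic vascular territory shapes. Passing phantom tests therefore
validates the measurement and scoring machinery, not clinical accuracy.

**Tabular cohorts** draw per-region infarct labels from per-region
prevalences (defaults: the final-infarction frequencies observed in an
external 143-patient LVO validation cohort — caudate 0.36, insular cortex
0.43, internal capsule 0.25, lentiform nucleus 0.43, M1 0.15, M2 0.31,
M3 0.12, M4 0.13, M5 0.16, M6 0.13) and rHU from class-conditional
Gaussians truncated at zero, means 0.87 (infarcted) / 0.97 (non-infarcted),
common SD 0.05. Gaussians are the minimal model matching a mean/SD
parameterisation; under it the theoretical AUC is Φ(0.10/√(2·0.05²)) =
Φ(√2) ≈ 0.921, which the acceptance checks use as a closed-form oracle.
Labels are drawn independently across regions, so the simulated cohorts
carry no spatial correlation between neighbouring regions and no
patient-level severity factor; patient-level outcomes (`simulate_outcomes`)
add a weakly informative logistic link from infarct burden to 3-month poor
outcome, a reader-error model for visual ASPECTS (rounded Gaussian error,
SD 1.5 points), and infarct volume proportional to infarcted-region count
(18 mL per region, 25 mL noise). These choices produce the weak
outcome-discrimination regime reported for admission imaging scores, but
they are stylised: correlations measured on simulated cohorts characterise
the estimators, not the clinical effect sizes.

Default cohort sizes are 368 (training) and 143 (validation), matching the
two-centre design the pipeline targets. All generators are bit-reproducible
given a seed.

## Problem sizes and runtime

The default test suite and `scripts/acceptance.py` use the sizes above
(368/143 cohorts, 64×64×40 phantoms, 2000-replicate bootstraps, 500
simulations × 1000 replicates for the type-I-error check); the full
acceptance run completes in well under a minute on one CPU, the test suite
in about half a minute.

## Known limitations

- The pipeline consumes registration transforms; it does not compute them.
  Registration quality directly biases rHU and overlap fractions.
- The atlas is treated as ground truth; disagreement between atlas
  definitions is known to move regional metrics.
- Cut points learned on one scanner/protocol mix need external validation
  before reuse; the package ships no clinical cut points.
- The S1-style XLSX importer is mapping-driven and performs no semantic
  validation beyond region-name normalisation and dtype coercion.
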