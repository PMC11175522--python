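# ctaspects

Automated detection of early irreversible ischemic change on CT-angiography
source images for patients with large vessel occlusion (LVO) stroke.

The Alberta Stroke Program Early CT Score (ASPECTS) deducts one point for
each of ten middle-cerebral-artery territory regions showing early ischemic
change — three subcortical (caudate, internal capsule, lentiform nucleus)
and seven cortical (insular cortex, M1–M6). `ctaspects` scores CTA source
images automatically:

1. **Region measurement.** A 20-mask atlas (10 regions × 2 hemispheres) in
   template space is resampled onto each patient's CTA via a supplied
   affine transform. For each region on the occluded side, the *relative
   Hounsfield unit* is the ratio of mean attenuations,

   rHU = mean HU(region, occluded side) / mean HU(mirror region, contralateral side),

   with only voxels in the inclusive window [1, 250] HU contributing —
   the ratio normalises contrast-bolus timing, the window rejects air,
   bone and dense vessels leaking through imperfect coregistration.
2. **Ground truth.** On follow-up diffusion-weighted MRI after successful
   thrombectomy, a region counts as finally infarcted when ≥ 30% of its
   voxels intersect the manually segmented lesion mask (evaluated as an
   exact voxel-count ratio); DWI-ASPECTS is 10 minus the infarcted count.
3. **Threshold model.** Per region, the rHU cut point t* maximising the
   Youden index J(t) = sensitivity(t) + specificity(t) − 1 is learned on a
   training cohort ("infarcted" predicted when rHU < t*), with
   patient-level 10-fold cross-validation.
4. **Evaluation.** Per-region AUC / accuracy / sensitivity / specificity on
   an external cohort; Spearman r_S of the threshold-based ASPECTS against
   DWI-ASPECTS and final infarct volume (percentile-bootstrap 95% CI);
   Wilcox's percentile bootstrap for comparing two dependent overlapping
   correlations (automated vs. a radiologist's visual ASPECTS); DeLong's
   paired test for AUCs predicting poor functional outcome (3-month mRS > 2).

A synthetic module generates mirror-symmetric CTA/DWI phantoms and tabular
cohorts with known planted truth, so the whole pipeline is testable without
clinical data.

## Worked example

Fit cut points on a simulated 368-patient training cohort and
cross-validate (`examples/02_fit_and_crossvalidate.py`):

```text
region            cut point   Youden J   n
Caudate              0.936      0.70  368
InternalCapsule      0.905      0.69  368
LentiformNucleus     0.940      0.67  368
InsularCortex        0.929      0.74  368
M1                   0.924      0.71  368
...
10-fold CV (seed=1): auc 0.92+/-0.05, accuracy 0.84+/-0.07, sensitivity 0.86+/-0.14, specificity 0.83+/-0.08
```

Every cut point lands between the simulated class means (infarcted rHU
0.87, non-infarcted 0.97); the CV line is the mean ± SD of each metric over
all 10 regions × 10 held-out folds. `examples/01_phantom_pipeline.py` runs
the volumetric path on a phantom (a planted M1 multiplier of 0.85 is read
back as rHU 0.850 exactly at zero noise) and
`examples/03_external_validation.py` adds the external-validation
statistics.

## Command line

The same stages are exposed as a thin CLI for batch runs driven by a
manifest CSV (one row per patient: id, file paths, occlusion side):

```sh
ctaspects simulate --kind phantom --out-dir scratch/ph --seed 1
ctaspects extract  --manifest manifest.csv --atlas atlas_dir --out rhu.csv
ctaspects label    --manifest manifest.csv --atlas atlas_dir \
                   --out labels.csv --patients-out patients.csv
ctaspects train    --table merged.csv --model-out model.json --report-out cv.json
ctaspects evaluate --model model.json --table validation.csv \
                   --metrics-out metrics.csv --report-out report.json
ctaspects import-xlsx --xlsx measurements.xlsx --mapping mapping.yaml --out table.csv
```

Volumes are NIfTI-1; transforms are plain 4×4 world-mm affine text files
(FSL FLIRT's native scaled-voxel `.mat` convention is not parsed — convert
first). `import-xlsx` converts a deposited measurement workbook to the tidy
region table through a user-supplied column mapping.

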