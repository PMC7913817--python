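# opqct — opportunistic QCT screening on routine CT

`opqct` re-implements, as a tested end-to-end pipeline, an opportunistic
osteoporosis-screening workflow for routine contrast-enhanced multi-detector
CT (MDCT): phantom-calibrated trabecular bone mineral density (BMD) at every
vertebral level Th5–L5, subcutaneous/visceral adipose tissue (SAT/VAT)
quantification at L4/5, and the matched case-control statistics that rank
vertebral levels as predictors of incident osteoporotic vertebral fractures.

It is written for researchers in quantitative CT and opportunistic screening
who need a fully testable stand-in for patient scans: a synthetic-CT and
synthetic-cohort generator with exact voxel-level ground truth replaces the
(non-public) clinical data, so every measurement stage can be validated
against a known answer.

## The method

**Synchronous calibration.** A two-phase density reference phantom in the
table mat is scanned with the patient. Sampling mean HU in each phase and
fitting the line through the two (HU, density) points gives a per-scan
conversion

&nbsp;&nbsp;&nbsp;&nbsp;BMD [mg/cm³] = a·HU + b,

which absorbs scanner drift. Trabecular BMD is then measured in a circular
ROI on the mid-sagittal slice of each vertebral body (3 mm sagittal
reformation): diameter standardized to ⅔ of the vertebral height, centre
equidistant to both endplates at the centroid of the anterior trabecular
half, excluding cortical shell, endplates and the basivertebral venous
plexus. Vertebrae with a prevalent fracture are never measured. The
QCT-standard comparator is the mean over L1–L3.

**Adiposity.** Five 
axial slices centred on the L4/5 disc are segmented by
threshold + region growing: fat-range voxels (−190…−30 HU by default) between
the cutis and the muscle wall are SAT; fat-range voxels inside the inner
muscular border, excluding muscle and contrast-filled bowel, are VAT.

**Statistics.** Matched pairs are compared with the exact Wilcoxon
signed-rank test; associations use Spearman correlation; discrimination of
fracture cases from controls uses the nonparametric (Mann–Whitney) AUC with
Hanley–McNeil standard error and a normal test against AUC = 0.5; effect
sizes are odds ratios per SD decrease from logistic regression; multivariate
selection is forward stepwise logistic regression with score-test entry at
p < 0.05.

## Worked example

```python
from opqct import generate_scan, calibrate_scan, measure_spine, measure_fat
from opqct.synth import scaled_specs

geometry, body, phantom = scaled_specs(1.0)
volume, truth = generate_scan(geometry, body, phantom, noise_sd=20.0, seed=7)

model = calibrate_scan(volume, phantom)
print(f"calibration: BMD = {model.slope:.4f} * HU + {model.intercept:.2f}")

spine = measure_spine(volume, model, prevalent_fractures={"Th12"})
for m in spine.measurements[:3]:
    print(f"{m.level}: {m.bmd:.1f} mg/cm3 (true {truth.true_densities[m.level]:.1f})")
print(f"mean L1-L3: {spine.mean_l1_l3:.1f} mg/cm3 ({spine.l1_l3_flag})")

fat = measure_fat(volume)
print(f"SAT {fat.sat_cm3:.1f} cm3 (true {truth.sat_volume_cm3:.1f}), "
      f"VAT {fat.vat_cm3:.1f} cm3 (true {truth.vat_volume_cm3:.1f})")
```

prints

```
calibration: BMD = 1.2457 * HU + 0.26
Th5: 175.0 mg/cm3 (true 176.4)
Th6: 163.4 mg/cm3 (true 165.3)
Th7: 168.9 mg/cm3 (true 166.3)
mean L1-L3: 132.0 mg/cm3 (complete)
SAT 115.6 cm3 (true 115.6), VAT 100.9 cm3 (true 100.9)
```

The fitted line recovers the generator's internal HU→density mapping (slope
1.25) up to phase-sampling noise; per-level BMD lands within measurement
noise of the true densities; Th12, flagged as a prevalent fracture, is
skipped; SAT/VAT volumes match the voxel-level ground truth.

The statistical battery runs on a cohort table (one row per subject):

```python
from opqct.reference import reference_cohort_params
from opqct.synth import generate_cohort
from opqct.stats import build_report

report = build_report(generate_cohort(reference_cohort_params(), seed=11))
```

For that seed the discrimination table reads `Th7: AUC 0.920 ± 0.050
(p = 0.000)`, `L1-L3: AUC 0.855 ± 0.067`, `VAT: AUC 0.516 (n.s.)`,
`SAT: AUC 0.370 (n.s.)` — one 17 + 17 draw from the reference group
parameters, in which thoracic BMD separates the groups strongly while the
adiposity measures carry no signal.

The same stages are available from the shell:

```bash
opqct run-all --seed 1 --out demo_run        # simulate → calibrate → measure → segment → analyze
opqct simulate-scan --out scan.nii.gz --seed 3
opqct calibrate --scan scan.nii.gz --out cal.json
opqct measure-bmd --scan scan.nii.gz --calib cal.json --fractures Th12,L2 --out bmd.csv
opqct segment-fat --scan scan.nii.gz --out fat.json
opqct simulate-cohort --out cohort.csv
opqct analyze --cohort cohort.csv --out report/
```

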