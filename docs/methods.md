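# Methods

This note documents the models, parameter choices and numerical conventions
behind `opqct`, and what the synthetic data do and do not establish about
behaviour on real scans.

## Synthetic CT model

The generator renders a parametric trunk in Hounsfield units on a regular
voxel grid. Axes are ordered (sagittal, coronal, axial), right-handed, with
the position of voxel *(i, j, k)* at *(i·sx, j·sy, k·sz)* mm; default spacing
is 1.5 × 1.5 × 2.5 mm.

**Spine.** Thirteen vertebral bodies Th5–L5 are elliptic cylinders with flat
endplates, stacked along the axial axis with a 4 mm intervertebral gap.
Default heights grow linearly from 22 mm (Th5) to 28 mm (L5). The
antero-posterior trabecular semi-axis is set to 0.75·height so the
standardized ⅔-height ROI circle fits in the anterior trabecular half with a
margin; the cortical shell is 2.5 mm, endplates 2 mm, and the basivertebral
venous channel is a 2 mm-radius cylinder running antero-posteriorly through
the posterior half at mid-height (it pierces the posterior shell, as the real
channel does). These shapes are deliberately simple: their purpose is to
exercise the ROI exclusion rules against an exact label mask, not to imitate
vertebral anatomy.

**Body composition.** The abdominal cross-section is a nest of ellipses:
cutis (2.5 mm, +30 HU), subcutaneous fat ring (17 mm), muscle wall (9 mm,
+50 HU), and a visceral compartment containing a contrast-filled bowel/organ
ellipse (+150 HU) and visceral fat; a paravertebral muscle ellipse around the
spine closes the inner border posteriorly. Adipose tissue renders at
−100 HU. The topology guarantees the segmentation contract: SAT encloses the
muscle wall, which encloses VAT.

**Phantom and HU model.** The density reference phantom is two full-length
cylinders in the table mat below the back, with known densities (default 0
and 200 mg/cm³) rendered at their nominal HU (default 0 and 160). The two
(nominal HU, density) points *define* the scanner line; trabecular bone of
true density ρ renders at the inverse of that line, so synchronous
calibration can recover ρ exactly in the noise-free case. Cortical bone and
endplates render as 650 mg/cm³ through the same line; the venous channel
renders at +150 HU (contrast-filled).

**Contrast enhancement and noise.** Intravenous contrast is modelled as a
scan-wide additive HU offset applied to all anatomy but *not* to the phantom,
which sits outside the vascular compartment — synchronous calibration
therefore corrects scanner drift but not tissue enhancement, and an offset
propagates into measured BMD (slope × offset, ≈ 44 mg/cm³ for a 35 HU offset).
This is the physically expected behaviour of opportunistic BMD on enhanced
scans; correction models for it are out of scope. Noise is additive i.i.d.
Gaussian HU noise, default SD 20 HU, chosen as representative of trabecular
bone noise at 120 kVp / ~200 mAs. No beam hardening, scatter or partial
volume is modelled. All randomness flows from a single integer seed;
identical inputs give bit-identical volumes.

**Ground truth.** Every voxel carries exactly one tissue label. True SAT/VAT
volumes over the L4/5 window are defined as label count × voxel volume, which
is the same discretization the measurement uses — noise-free recovery is
therefore exact by construction, and the recovery tests quantify the effect
of noise alone.

## Synthetic cohorts

Scalar cohorts emulate a matched case-control design: per pair, age and
follow-up are shared (±1 y jitter), mirroring age/sex/follow-up matching.
Per-level BMD is multivariate Gaussian within group with an exchangeable
inter-level correlation (default ρ = 0.7, in the middle of the 0.445–0.855
range of reported inter-level correlations); group means and SDs default to
the reference study's printed values. The distributional family is a
modelling choice — the study reported mean ± SD only, and noted non-normality
for most parameters; Gaussian is the minimal stand-in. SAT and VAT are
zero-truncated Gaussians (their SDs are of the order of their means, so an
untruncated Gaussian would put ~5–15% of mass below zero); truncation raises
the effective mean (≈ +45 cm³ for SAT), which the moment tests account for
analytically. VAT and SAT are sampled independently of BMD; the reference
analysis found only weak VAT–BMD correlations at L1/L2, and none of the
acceptance quantities depends on that cross-correlation. The per-subject
VAT/SAT ratio and the mean over L1–L3 are always computed from the simulated
values, never drawn.

## Measurement conventions

* **Mid-sagittal slice:** nearest slice to the body-centre x-coordinate;
  an exact midpoint ties toward the lower index.
* **3 mm reformation:** the ROI mean is taken over the contiguous native
  sagittal slices spanning 3 mm centred on the mid-sagittal slice
  (2 slices at the default 1.5 mm spacing).
* **Circle discretization:** a voxel belongs to the ROI iff its centre lies
  inside the circle, so voxel counts are reproducible.
* **Placement:** the circle centre sits at mid-height and at the centroid of
  the anterior trabecular half (the anterior half is defined by the
  antero-posterior midline of the body ellipse). A 0.75 mm safety margin
  against shell, endplates and plexus absorbs boundary discretization; the
  margin also accounts for the slightly narrower trabecular ellipse seen by
  the off-midline reformation slices. If the standardized circle cannot fit,
  it shrinks to the largest admissible circle (recorded on the ROI); below a
  4 mm diameter, placement fails.
* **Mean L1–L3 with missing members:** the mean over the remaining levels is
  reported with a `partial` flag (with none, `missing`); the source protocol
  only states that fractured vertebrae are not measured.
* **Phantom sampling:** per phase, a cylindrical ROI of 80% phase radius and
  full length minus one voxel per end, emulating central manual placement
  away from partial-volume rims. Two-point fits interpolate exactly;
  ≥3 phases fall back to ordinary least squares.
* **Reproducibility %CV:** repeated full re-measurements (fresh noise, fresh
  calibration) of the same anatomy; at default noise this lands at 1–2.5%
  per level, inside a (0.3, 10)% plausibility band that contains the
  published 2.09–7.70% re-measurement error range. The published range also
  includes operator variability, which a noise-only re-measurement cannot
  reproduce, hence a band rather than a gate.

## Fat segmentation

Slices are processed independently in 2-D with 4-connectivity (the protocol
quantifies a 5-slice window, not a whole-abdomen 3-D volume). The body is
the largest connected component above −400 HU, hole-filled. Voxels above the
adipose upper bound act as the growth barrier; region growing from two
automatically chosen seeds (the free voxel nearest the body centroid for
VAT; the first free voxel under the anterior cutis for SAT) partitions the
remaining voxels, replacing the "manually assisted" interaction of the
original workflow. Seeds are restricted to free components of ≥25 voxels so
additive noise cannot strand a seed in a pinched-off pocket. If the two
grown regions merge, the muscle wall is open and a leak error reports the
approximate breach (the corridor voxel between the seeds most hemmed in by
barrier). Contrast-filled bowel excludes itself by threshold (far above the
adipose range). The adipose range defaults to −190…−30 HU and is
configurable. Volumes are cm³ over the 5-slice window; the VAT/SAT ratio is
per subject and undefined (flagged) when SAT is zero.

## Statistics

* **Wilcoxon signed-rank (paired):** pairing key is the matched-pair id —
  the matching is what justifies a paired test on a case-control table.
  Zeros are dropped. The null distribution is exact for ≤25 nonzero pairs,
  computed by convolution over doubled mid-ranks (exact even under ties);
  beyond that, a normal approximation with tie and continuity corrections.
  Two-sided p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))). All differences zero
  yields a degenerate, flagged p = 1.
* **AUC:** Mann–Whitney pair statistic, ties ½. Reported SE is
  Hanley–McNeil at the observed AUC; the p-value against 0.5 uses the
  null-hypothesis variance (n₀+n₁+1)/(12 n₀ n₁), to which Hanley–McNeil
  reduces at AUC = 0.5. Orientation (lower- vs higher-value-indicates-case)
  is explicit in every result; BMD defaults to lower-indicates-case,
  adiposity to higher-indicates-case.
* **Odds ratios:** univariate logistic regression on the standardized,
  orientation-signed predictor; scaling uses the pooled-sample SD (the
  source does not say which SD; pooled is the documented, configurable
  choice), so OR = exp(β) per SD decrease. Complete separation is flagged
  with an infinite CI rather than a spurious estimate.
* **Stepwise logistic regression:** forward selection; entry by Rao score
  test of the candidate added to the current fit (computed via the
  efficient-score formula from the reduced-model fit), threshold p < 0.05,
  ties by listed order; the final model is refit and reported with Wald
  p-values and per-SD-decrease ORs. An empty model is a valid outcome. The
  reference software's selection flavour (LR vs Wald entry) is unstated;
  score-test entry is the documented choice.
* **No multiplicity correction** anywhere, matching the reference analysis
  (each test two-sided at 0.05).

## What passing tests show — and do not show

The synthetic scans have piecewise-constant tissues, exact geometric
borders, no partial volume, no beam hardening and stationary Gaussian noise.
Passing recovery tests therefore demonstrates that the *algorithms* are
correct against their own geometric contracts and robust to additive noise —
not that they would segment real abdominal CT, where partial volume, bowel
gas, table artefacts and anatomical variation dominate. Likewise the
synthetic cohorts are Gaussian by construction, whereas the real parameters
were mostly non-normal; AUC coverage checks compare sampling distributions
under this stand-in family. Vertebra detection/labelling is out of scope:
synthetic scans carry their geometry as metadata, standing in for the manual
level identification a radiologist performs.

## Problem sizes used by the test suite

Chosen as the package's own validation budget: 50 full-size scans for ROI
purity/bias, 15 re-measurements for %CV, 2 seeds × 2 noise levels for fat
recovery, 1000/40/50 random cases for the AUC/Wilcoxon/Spearman brute-force
oracles, 2000 simulated cohorts of 17+17 per AUC coverage target, and 500
replicate cohorts for the adiposity null checks. The central-limit check of
the generator runs 300 seeds on a reduced-scale volume with a coverage bound
loosened from the asymptotic 99.73% to 98.5% to allow for binomial
fluctuation at that replicate count.
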