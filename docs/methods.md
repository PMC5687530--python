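# Methods

This note documents the models, numerical choices and limitations behind
`qctlung`. It is written for a reader who wants to know exactly what each
number the package emits means, and what passing the test suite does and does
not demonstrate.

## Problem setting

Obstructive airway disease alters the lung at two scales visible in paired
inspiratory/expiratory CT: airway geometry (luminal narrowing, wall
thickening, loss of circular cross-section) and parenchymal density/mechanics
(emphysematous destruction, expiratory air trapping, reduced regional
deformation). `qctlung` implements a panel of nine such metrics — three
airway metrics over ten named airway regions and six lobar/parenchymal
metrics over five lobes — together with the three-group (healthy / asthma /
COPD) nonparametric comparison used to contrast them, and a synthetic
phantom generator that supplies inputs with exactly known ground truth in
place of clinical scans, which are typically not redistributable.

## Airway morphometry

Inputs are per-branch lumen area `A` (mm²), perimeter `P` (mm) and wall
thickness `WT` (mm), as produced by airway segmentation software. We compute

* circularity `Cr = 4πA/P²` — equal to 1 for a circle and strictly below 1
  otherwise (the isoperimetric inequality `P² ≥ 4πA` is enforced on input;
  violations indicate inconsistent measurements and raise);
* hydraulic diameter `Dh = 4A/P` (mm).

`Dh` and `WT` are normalised into dimensionless starred values by dividing
by the subject's *predicted healthy tracheal* value, from an OLS model on
`[1, sex, age, height]` fitted to healthy subjects only. Sex dominates
inter-subject airway-size variation, so this removes body-size confounding
while leaving disease effects in place. A linear OLS form was chosen as the
simplest model consistent with that observation; the fitted residual scale is
stored for diagnostics, and rank-deficient designs fail loudly naming the
collinear covariates. Predictions must be strictly positive; non-positive
predictions (covariates far outside the fitting hull) raise rather than
silently producing negative normalisations.

Region aggregation over the ten regions (trachea, RMB, LMB, BronInt, TriLLB,
sLUL, sRUL, sRML, sLLL, sRLL) is an unweighted mean of a subject's branch
values per region; a region with no branches is reported absent, never
imputed as zero.

## Fraction-threshold densitometry

HU maps to an air fraction linearly between two references,
`β_air = (hu_tissue − HU)/(hu_tissue − hu_air)` clamped to [0, 1], with
`β_tissue = 1 − β_air` exactly. Defaults are `hu_air = −1000`,
`hu_tissue = +55` (conventional pure-air and soft-tissue values; both are
configuration fields, not constants). Thresholding the *fraction* rather
than raw HU removes affine scanner-calibration differences: shifting the HU
data and references together leaves every fraction unchanged (tested).

* `Emph%`: percent of masked inspiratory voxels with `β_air > 0.985`.
* `fSAD%`: percent of masked expiratory voxels with `β_air > 0.90` that are
  *not* emphysematous on the co-registered inspiratory map
  (warped `β_air ≤ 0.985`) — the parametric-response-map subtraction that
  separates functional small-airway disease from emphysema.
* `β_tissue`: mean tissue fraction per lobe at inspiration.

With the default references the fraction thresholds are algebraically
equivalent to HU cutoffs of −984.175 (emphysema) and −894.5 (trapping),
asserted in tests by inverting the fraction formula. Percentages are
voxel-count based; since voxel volume is constant within an image this
coincides with volume weighting (it would not on mixed-resolution inputs,
which the containers do not represent). Voxels whose warped inspiratory
sample falls outside the inspiration domain are excluded from both numerator
and denominator. The expiration acquisition state (FRC vs RV) is recorded in
the configuration for reporting only; no correction is applied.

## Deformation metrics

The displacement field `u(x)` maps expiration-grid points to inspiration
space (`fixed` = expiration, `moving` = inspiration); all deformation
metrics live on the expiration grid and `J > 1` means expansion toward
inspiration. From `F = I + ∂u/∂x` (spacing-scaled central differences
interiorly, one-sided at the boundary):

* Jacobian determinant `J = det F`, the local volume-change factor.
  Non-positive values inside the lung (registration folding) are warned
  about and flagged.
* Principal stretches `λ1 ≥ λ2 ≥ λ3` are singular values of `F` (square
  roots of the eigenvalues of `FᵀF`), so rigid rotations give exactly
  (1, 1, 1).
* `ADI = sqrt(((λ1−λ2)/λ2)² + ((λ2−λ3)/λ3)²)`, zero for isotropic or rigid
  motion, growing with directional preference.
* Fractional lobar air-volume change: per voxel of volume `v`, the air
  gained toward inspiration is `v·(J·β_air,insp(x+u) − β_air,exp(x))`; each
  lobe's sum is divided by the whole-lung sum, so lobar fractions add to 1
  by construction. A non-positive whole-lung total raises, since it almost
  always means the inspiration/expiration inputs were swapped.

Interior central differences are second order; the one-voxel boundary shell
(first-order one-sided stencils) is excluded from lobar summaries. Grid
refinement tests confirm roughly fourfold error reduction per halving of the
spacing against an analytic sinusoidal field.

Scalar warping uses trilinear interpolation at `x + u(x)`; out-of-domain
samples become NaN and are excluded downstream.

A bundled multi-resolution demons (diffusion-regularised) estimator can
produce `u` from the image pair when no external registration is available.
It is deliberately simple — shrink-factor pyramid, symmetric-forces demons,
Gaussian field smoothing — deterministic given its parameters, and aborts if
the image dissimilarity increases. Any externally computed field in the same
NIfTI layout is accepted in its place; the ground-truth phantom field, not
the estimator, is the primary validation path.

## The phantom generator

The generator's purpose is closure: every downstream metric applied to a
noise-free phantom must return the value the phantom prescribes. Design
choices serving that purpose:

* **Geometry.** The five lobes are disjoint axis-aligned blocks inside a
  32³ grid at 2 mm spacing (both configurable). Block geometry keeps voxel
  counts, class fractions and the deformation ground truth exact and tests
  fast; nothing anatomical is claimed.
* **Class placement.** Emphysema voxels are placed on the *inspiration*
  grid (where Emph% is measured) and air-trapping voxels on the
  *expiration* grid (where fSAD% is measured), each as contiguous slabs at
  opposite ends of every lobe with exactly `round(pct/100 · N_lobe)`
  voxels. Class air fractions default to 0.88 (parenchyma at TLC), 0.995
  (emphysema) and 0.95 (trapped at expiration), chosen to sit on the correct
  sides of the 0.985/0.90 thresholds under the default deformation.
* **Deformation.** The prescribed field is affine (about the grid centre)
  plus a cross-axis sinusoid, with analytic `F` and `J`. The default is a
  uniform volumetric expansion of 1.3 plus a 1.5 mm sinusoid. Configs whose
  displacement-gradient norm reaches 1 (non-invertible) are rejected with a
  diagnostic.
* **Mass-consistent expiration image.** The expiration scan is the TLC scan
  pulled back through the field with tissue mass conserved:
  `β_tissue,exp(x) = J(x)·β_tissue,insp(x+u(x))`. Air-trapped voxels then
  *override* this with their high retained air fraction — trapping is
  exactly a local failure of uniform deflation, so the override is the
  physiology, not a shortcut. Consequently the global tissue-mass
  conservation property is asserted on trapping-free phantoms (it holds to
  machine precision under rigid motion and to interpolation error
  otherwise), and the generator books the true lobar air-volume change from
  the air it actually placed, analytic Jacobian included.
* **Noise.** Additive Gaussian HU noise (default sd 20 HU, a typical
  parenchymal noise level) is applied last, after all bookkeeping, so
  prescribed percentages always refer to the noise-free field. All tests of
  exact recovery switch noise off explicitly.
* **Exactness domain.** On a deformation-free, noise-free phantom, Emph%
  and fSAD% recovery is exact to the voxel-rounding of the prescribed count
  (±0.5 percentage points covers any lobe size ≥ 100 voxels). Under
  deformation, Emph% remains exact (its classes live on the measured grid)
  while fSAD% additionally picks up partial-volume voxels at
  emphysema-slab interfaces — which is faithful to how the subtraction
  behaves at real emphysema borders, and shrinks with grid resolution.
* **Seeding.** One global seed fans out into named substreams
  (per-component, per-metric), so adding a component or metric never
  perturbs earlier draws, and identical configs are bit-identical.

## Cohort generator and group comparison

The cohort generator draws per-subject metric values from Gaussian baselines
with group-specific location shifts and scale factors. Baselines and the
default effect table are *direction-calibrated*, not magnitude-calibrated:
published group summaries do not include per-subject variances for most
imaging metrics, so magnitudes were chosen once as clinically plausible
values and are not fitted to any source. The defaults encode: emphysema and
trapping burden COPD > asthma > healthy (e.g. fSAD% 18 vs 10 vs 5 on
average); tissue fraction and Jacobian COPD < asthma < healthy; airway
circularity and normalised calibre reduced in both disease groups; ADI
reduced more in COPD. Group sizes default to 50 per group; demographic ages
follow the three cohorts' reported means (healthy 50.7 ± 17.2, asthma
48.7 ± 11.2, COPD 67.1 ± 7.2 years), and the airway generator derives
branch geometry from a known linear tracheal-size model so the
normalisation machinery can be validated by parameter recovery.

The comparison family mirrors the study design: per metric × region a
Kruskal-Wallis omnibus test (mid-rank tie correction, χ² approximation,
df = k−1) plus the three pairwise Mann-Whitney contrasts, with
Benjamini-Hochberg step-up control applied once across the *entire* emitted
family at q = 0.01. The pairwise statistic is a design choice — the
procedure is specified only as a rank-based post-hoc with BH control — and
the family size is logged with every run rather than assumed. Pairwise
significance is annotated `*` (healthy vs asthma), `†` (asthma vs COPD),
`‡` (COPD vs healthy). Pearson's χ² (no continuity correction) is provided
for categorical tables. Degenerate all-tied samples return H = 0, p = 1
flagged rather than erroring.

The FDR simulation draws global-null cohorts whose family has exactly 87
omnibus tests (87 independent standard-normal variables; the enumeration
behind the original 87-test family is not published, so the simulation
matches its width with the simplest independent family) at the three
cohorts' actual group sizes, and estimates the FDR as the fraction of
cohorts with at least one rejection — under the global null every rejection
is false. With 500 cohorts the binomial 95% CI half-width at a true rate of
1% is about 0.9 percentage points.

## Problem sizes used

Defaults were chosen so the full validation cycle runs on a laptop-class
machine: 32³ phantoms, 500-cohort FDR simulations, 100-seed power checks at
50 subjects per group. All sizes are configuration fields and scale up
unchanged.

## Known limitations

* Block-lobe phantoms contain no airway tree geometry, no realistic CT
  texture and no scanner/kernel effects; passing closure tests validates the
  *estimators*, not their robustness to real-scan artefacts.
* The demons estimator is a convenience, not a production registration; on
  texture-free regions it returns the regularised (near-zero) field, and its
  accuracy claims are limited to the smooth, textured test cases.
* The cohort effect table is direction-only; absolute group means emitted by
  the comparison report should not be read as population estimates.
* FRC-vs-RV expiration differences are recorded but not modelled; fSAD% and
  Jacobian comparisons across acquisition protocols inherit that caveat.
* Covariate adjustment (age, BMI differ between groups) is deliberately out
  of scope of the comparison; tests are marginal rank tests.
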