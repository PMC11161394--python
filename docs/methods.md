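# Methods

`surfload` implements a two-arm surface-based analysis of intracortical
T1w/T2w ratio (a proxy for intracortical myelin content) in a two-group
cross-sectional cohort, together with a synthetic-cohort generator used to
validate every stage.  This note documents the models, the numerical
choices, and what the synthetic benchmarks do and do not show.

## Subject-level arm: normative outlier mapping

Each subject's per-vertex ratio map is standardized against the
typical-comparison (TC) group:

    z_v = (x_v − mean_v) / sd_v

where `mean_v` and `sd_v` are the vertex-wise sample mean and sample SD
(n−1 denominator) over the TC maps.  When the scored subject is itself a TC
member, the statistics are recomputed with that subject left out, so no map
is compared against a reference that contains it.  The leave-one-out
statistics are obtained by direct recomputation per excluded subject; at
reference sizes of a few dozen this costs nothing and avoids the cancellation
error of running-sum updates.

z-maps are smoothed at 10 mm FWHM, thresholded at |z| ≥ 2, and the
suprathreshold vertices of each sign are partitioned into edge-connected
components.  Components whose summed vertex area falls below the extent
threshold `min_area` are discarded.  A subject's HR-load (LR-load) is the
total area of surviving high-ratio (low-ratio) clusters, pooled over
hemispheres; HR+/LR+ status means a nonzero load.  Vertex area assigns one
third of each triangle's area to each corner, which makes cluster areas sum
exactly to the mesh area they cover.

Decisions where the procedure is underdetermined:

* **Smoothing order.**  The z-maps are smoothed after standardization
  (`smooth_target="zmap"`, following the stated order of the steps);
  smoothing the input ratio maps before z-scoring is available as
  `smooth_target="input"`.  Smoothing a unit-variance z field shrinks its
  marginal SD by roughly `fwhm_noise / sqrt(fwhm_noise² + fwhm_smooth²)`,
  so the expected |z| ≥ 2 rate falls below the Gaussian 2Φ(−2) ≈ 4.55% by an
  amount that depends on the spatial smoothness of the between-subject
  variation; the leave-one-out t-inflation (z/√(1+1/n) ~ t with n−1 df)
  pushes it up.  Both effects are visible in the null calibration below.
* **Extent threshold.**  No canonical value exists; the default is
  `min_area = 50 mm²`, large enough to remove single-vertex noise at the
  mesh resolutions used here, and it is echoed into every output manifest
  because results are not interpretable without it.
* **Hemispheres** are processed with independent normative statistics and
  loads are summed across them.
* **No covariate adjustment** is applied in the z-maps; covariates enter the
  group-level arm only.

## Group-level arm: permutation GLM

At every vertex, ordinary least squares fits

    ratio ~ intercept + group + age_c + group×age_c + PRI + TBV + CNR

with age centered at the sample mean.  PRI is nonverbal IQ (perceptual
reasoning index), TBV total brain volume (cm³), CNR the gray–white
contrast-to-noise ratio — nuisance covariates for scan and subject quality.
The design is checked for full column rank (collinear columns are named) and
requires n ≥ p + 2 rows.

Family-wise error over vertices is controlled by the max-statistic
permutation method under the Freedman–Lane scheme: the nuisance columns
(everything outside the tested contrast) are regressed out of the data, the
residualized rows are permuted, the full model is refit, and the maximum |t|
over vertices is recorded per permutation.  The corrected p-value of a
vertex is `(1 + #{permutation max ≥ observed |t|}) / (1 + n_perm)` for
Monte-Carlo sampling (the identity permutation is therefore always counted),
or the exact exceedance share when all n! permutations are enumerated
(`n_perm="exhaustive"`, feasible to n ≈ 7).  Uncorrected p-values are taken
from the same permutation distribution per vertex, which guarantees
corrected ≥ uncorrected everywhere.  Inference is two-sided; the per-vertex
direction is recorded in the t-map.  Sign-flipping is not used (errors are
not assumed symmetric), and exchangeability blocks are not implemented.

Clusters for reporting are connected components of FWE-corrected p < 0.05.
Each cluster's effect size is the partial R² of the tested term for the
area-weighted cluster-mean response: `(SSE_reduced − SSE_full) /
SSE_reduced` with the term dropped from the reduced model.  Because the
interaction column is collinear with age, age effect sizes are evaluated in
the main-effects model (no interaction term) — otherwise the age variance
splits between the two columns and the partial R² is not interpretable as
the age effect.

## Behavioral arm

Load distributions are compared between diagnostic groups with two-sided
Mann–Whitney U tests (exact enumeration when `n_x·n_y ≤ 400` and tie-free,
otherwise the normal approximation with tie and continuity corrections).
Because loads are zero-inflated, subjects are then split into
diagnosis-by-status subgroups and four planned contrasts are tested per
measure and arm: ASD+ vs ASD−, ASD+ vs TC−, ASD+ vs TC+, TC+ vs TC−.  The
default t-test is Welch's (unequal subgroup variances are the norm here);
Student's pooled test is available and the variant used is recorded in every
output row.  Spearman correlations relate load to each measure within the
outlier-positive subgroups (t approximation for p; exact permutation
available for n ≤ 8).  ADOS scores exist only for the diagnosis group and
are compared within it only.

FDR adjustment is Benjamini–Hochberg, applied per arm with the correlation
rows included in the family (`fdr_family="arm"`); a single global family is
available by pooling rows before adjustment.  Note that the step-up
adjustment is not idempotent — re-adjusting adjusted p-values is a mistake,
not a no-op.

Group matching mirrors the usual demographics table: Welch t for continuous
variables, chi-square for categorical, switching to Fisher's exact test for
2×2 tables with any expected or observed cell below 5.

## Surface smoothing

Smoothing is iterated graph diffusion: one step is `v ← v + λ D_a⁻¹ L v`
with `L` the uniform-weight graph Laplacian restricted to non-missing
vertices and `D_a` the diagonal of vertex areas.  Because `L` is symmetric
with zero column sums, every step conserves the area-weighted mean exactly;
`λ = 0.9·min(a_i/deg_i)` keeps each row a convex combination, so smoothing
never expands the value range.  Missing (NaN) vertices are cut out of the
graph (weights renormalize implicitly) and stay missing.

The iteration count targets a Gaussian kernel of the requested FWHM: one
step adds per-axis kernel variance `step_var = mean_i[(λ/a_i) Σ_j ℓ_ij²]/2`,
so the diffusion time is `t = (fwhm/2.3548)² / (k·step_var)`, run as ⌊t⌋
full steps plus one step with `λ` scaled by the fractional remainder (this
removes the integer-rounding error that dominates on coarse meshes).  The
calibration constant `k` was fixed at 1.0 after measuring the geodesic
second moment of delta responses on icospheres: the Gaussian-equivalent
FWHM (2.3548·σ from the second moment, the standard smoothness measure in
surface-based analysis) lands within 3–8% of the request across the mesh
resolutions used here.  The literal half-maximum width of a few-step
diffusion kernel can exceed the nominal FWHM by 10–20% on meshes whose edge
length approaches the kernel σ, because the kernel is flatter-topped than a
Gaussian; exact parity with any specific neuroimaging package's smoother is
not claimed.  On meshes coarser than the kernel, `t` rounds toward zero and
the map passes through (logged by the returned operator being near
identity).

## Synthetic cohort generator

A cohort is `base + slope·(age − mean age) + noise + patches` per subject
and hemisphere:

* **Base map**: a smooth field (40 mm FWHM, SD 0.10) around a ratio of 1.5,
  shared by all subjects — the large-scale myeloarchitectural pattern.
* **Age effect**: +0.002 ratio units/year (uniform ages 40–70), matching the
  order of magnitude of cross-sectional intracortical myelin aging effects.
* **Noise**: Gaussian fields with per-vertex SD 0.05.  White noise is passed
  through the smoothing operator and divided by the operator's exact row
  norms, so the marginal variance is exact at any mesh resolution.  The
  default correlation scale is 25 mm FWHM — between-subject variation in
  surface myelin maps is dominated by smooth anatomical and bias-field
  components; benchmarks that isolate geometric detection use rougher,
  weaker noise and say so.
* **Patches**: per subject, Poisson counts of high (rate 1.3) and low
  (rate 0.45) patches; each is a geodesic disk (graph-Dijkstra distances —
  an approximation that overestimates true geodesics by a few percent on a
  hexagonal mesh) of radius 10–20 mm, amplitude 4–6 noise-SD, flat core with
  a raised-cosine taper over the outer 30% of the radius (`taper_frac=0`
  gives a knife-edge disk).  The rates were calibrated so the *detected*
  outlier-positive shares reproduce the target design (~64% HR+, ~33% LR+).
  Poisson counts make the zero fraction `e^(−rate)` — the zero-inflation the
  load statistics must handle.
* **Phenotypes**: scores are drawn from unaffected base distributions (FSIQ
  112 ± 12.5; BRIEF GEC T 50 ± 10; DKEFS scaled 11 ± 3) and shifted in
  diagnosis-positive subjects that carry ≥ 1 high patch (FSIQ −15, BRIEF
  +18, DKEFS −5): deficits ride on the *carrier* state, not on the diagnosis
  label, so the battery's subgrouping is what must recover them.  ADOS
  totals are drawn for the diagnosis group only.  Informant availability is
  not modeled (all subjects have BRIEF scores).

All randomness flows from one integer seed through a single generator;
regenerating with the same configuration is byte-identical.

## What the benchmarks show — and what they don't

* **Null calibration** runs the full subject-level arm on a patch-free
  cohort (icosphere, subdivision 4, radius 30 mm ≈ 11,300 mm²): the mean
  |z| ≥ 2 fraction lands near 4% (t-inflation up, smoothing shrinkage down
  from 4.55%), and with `min_area = 100 mm²` most subjects are HR−/LR−.
  The second property is area-dependent: the expected number of surviving
  null clusters scales with total surface area, so on a full-size cortex
  (~180,000 mm²) a 100 mm² extent threshold would leave most subjects
  outlier-positive under a purely Gaussian null.  Real cortical data are not
  Gaussian at this level; the benchmark calibrates the machinery, not the
  biology.
* **Patch recovery** injects amplitude-5 (z units), radius-15 mm patches on
  icosphere(5, r = 100 mm) over weak rough noise and recovers them with mean
  Dice ≈ 0.8 and total recovered load ≈ 0.85 of total true area.  The
  systematic shortfall is real and expected: the |z| ≥ 2 contour sits inside
  the raised-cosine taper, so the detected disk is smaller than the full
  nonzero-amplitude support.  Per-subject load has irreducible variance from
  coincident noise clusters, which is why recovery is scored on cohort
  aggregates.
* **Permutation GLM type-I error** is checked over 200 null cohorts (n = 66,
  100-vertex mesh, 500 permutations) against the exact binomial band around
  5%.
* **Effect-size recovery** sets the age slope from the closed form
  `R² = b²·Var(age)/(b²·Var(age) + σ²)` (target 0.15 at n = 66) with
  cluster-common noise and recovers the mean partial R² within 0.05 (a small
  positive small-sample bias, ≈ (1−R²)/(n−p), is visible and expected).
* **Phenotype detection** runs the full chain — generate, outlier-map,
  subgroup, test, FDR — 100 times and requires the ASD-HR+ vs TC-HR+ FSIQ
  contrast to survive FDR in ≥ 80% of replicates (observed ≈ 0.93), with a
  null-effect cohort yielding well under 5% significant rows.

Passing these benchmarks demonstrates that the machinery is calibrated and
recovers known structure at desk scale.  It does not demonstrate anything
about real cortical data: the generator has no scanner artifacts, no
reconstruction failures, Gaussian (not heavy-tailed) between-subject
variation, spherical (not folded) geometry, and phenotype effects that are
cleanly confined to one subgroup.

## Problem sizes

Benchmarks run on icospheres of 642–10,242 vertices with cohorts of 56–66
subjects, 100–200 replicates for rate estimates, and 500 permutations per
GLM; these sizes keep Monte-Carlo error well inside the tested bands while
the whole validation suite completes in a few minutes on one CPU.
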