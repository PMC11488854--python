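# Methods

This note documents the statistical models implemented in `neuroaging`,
the synthetic data they are exercised on, the numerical choices that
matter, and what the validation results do and do not show.

## Trajectory model and deviation phenotypes

Each ROI's gray-matter volume is modeled per subject `i`, visit `t` as

    V_i(t) = beta0 + beta1 s + beta2 s^2 + gamma' x_i + b0_i + b1_i s + e_it,

where `s = (age - mean age) / 10` is the affine age transform (stored on
the fitted model; centering and the /10 rescaling keep the quadratic term
well conditioned over a ~40-year span), `x_i` are sex, site, handedness,
ethnicity (treatment-coded) and centered ICV, and `(b0_i, b1_i)` is a
bivariate-normal random intercept/slope with unstructured covariance.
Estimation is REML via statsmodels `MixedLM`; because mm^3-scale outcomes
put variance components near 1e9 and defeat gradient tolerances, the
outcome is standardized internally and every reported quantity
(coefficients, variance components, BLUPs, log-likelihood) is transformed
back to data units.  Optimizers are tried in the order L-BFGS, Powell,
BFGS; a model on exactly collinear or noise-free data short-circuits to
the OLS solution with zero variance components, which is the correct
degenerate limit.

Subject deviations at a reference age `a*` (default 60 y) are
`d_i(a*) = b0_i + b1_i s(a*)`; they are covariate-free because the fixed
part cancels.  The individualized total-GMV phenotype used for genetic
association adds `d_i(a*)` to the population fixed-effect prediction at
`a*` with covariates at reference levels.  Random-intercept vs
random-slope structures are compared by AIC/BIC computed from ML fits of
both candidates (REML likelihoods are not comparable across random
structures) together with the intra-class correlation
`sigma^2_b0 / (sigma^2_b0 + sigma^2_e)` of the RI model.

BLUPs at externally fixed variance components solve the mixed-model
normal equations per subject, `b_i = G Z_i' V_i^{-1} (y_i - X_i beta)`,
with `beta` the GLS solution at those components.  The validation suite
checks this against an independent dense-matrix implementation that
builds the full marginal covariance without per-subject blocking.

A caveat on shrinkage: the familiar inequality |BLUP slope| <= |per-subject
OLS slope| is a theorem only when intercept and slope estimation decouple
(visit times symmetric about the centering age, independent random
effects).  With correlated 2-D shrinkage the slope predictor borrows
information through the intercept channel and can exceed the OLS slope.
The test suite asserts the inequality in the decoupled regime.

## Pattern clustering

Deviations at 60 y form a subjects x ROIs matrix (40 ROIs by default: 33
bilaterally averaged cortical parcels plus 7 subcortical structures).
PCA is applied to the centered but unscaled matrix (all columns share
mm^3 units; variance-scaling would distort volumetric loadings), keeping
15 components by default.  k-means (k-means++ initialization, 20
restarts, fixed seed) clusters the scores; the elbow curve and the mean
silhouette over k = 2..8 are reported as diagnostics, with the silhouette
argmax as the recommendation.  For k = 2 the labels are permuted so that
pattern 1 is the cluster with the higher mean baseline total GMV (ties
broken by cluster size and recorded); this makes labels stable across
seeds and cohorts and matches the convention that pattern 2 is the
faster-declining group.

## Rate curves

Population (and per-pattern) volume-age curves are natural cubic
smoothing splines of covariate- and subject-adjusted volumes.  Subject
adjustment removes each subject's estimated random-effect trend but adds
back the group mean of those trends, so between-group contrasts survive
while within-group individual variation is absorbed (a two-stage
approximation to a full additive mixed model).  The penalty is selected
by GCV (default) or k-fold CV over a log-spaced grid; duplicate or binned
abscissae are pooled with multiplicity weights, the standard
smoothing-spline reduction.  Derivatives are analytic derivatives of the
B-spline basis, never finite differences, so the integral of the rate
over an interval reproduces the volume change exactly; effective degrees
of freedom (hat-matrix trace) tend to 2 in the heavy-penalty limit.
Effective df and leverage-based pointwise bands are computed lazily
because they cost one smoother application per distinct abscissa.

## Annual percentage volume change and mirroring

For every subject with at least two scans, `APC = 100 (V_last - V_first) /
(V_first dt)` in %/year from the first/last scan pair (one record per
subject keeps records independent).  The percentage normalization is
adopted deliberately: it is what "annual percentage change" means and
makes maps comparable across cohorts with different volume scales.
Per-ROI APC is regressed on the midpoint age of the scan pair — the
midpoint is the natural location for an interval-average rate — with a
smoothing spline whose penalty is chosen by 5-fold CV; midpoint ages are
binned to 0.25 y (weighted) before the banded solve.  Maps are evaluated
at 15 y (development) and 55/75 y (early/late aging); a target age within
1 y of a curve's fitted support is evaluated through the spline's
boundary extension, because scan-wave designs routinely leave the target
just outside the observed midpoint range.  Maps are standardized across
cortical ROIs with the sample SD (n-1), and the mirroring score is
`m_r = z_dev(r) - z_age(r)`, antisymmetric by construction; the Spearman
correlation of the two z-maps is reported alongside.

## Imaging transcriptomics

The first PLS component of the regions x genes expression matrix against
a cortical z-map uses the closed form for a univariate response: the
weight vector is `X' y` normalized (equivalently the leading right
singular direction of the cross-covariance), gene columns are z-scored
across regions first (removes expression-scale dominance), and the
component sign is fixed so the Spearman correlation between scores and
map is non-negative.  Explained variance is the R^2 of the map on the
first score — the response-side convention.  Note that "a gene identical
to the map" yields EV = 1 only when the remaining genes are orthogonal to
the map in-sample; with co-expressed genes the first component mixes
every column covarying with the map.

Spatial inference uses a rotation null: each permutation draws one
uniform random 3-D rotation, applies it to the left-hemisphere spherical
centroids and its x-mirrored conjugate to the right, and reassigns every
rotated parcel to the nearest original centroid within hemisphere.  The
mapping may repeat a source parcel (values are carried, not permuted
bijectively), the standard behavior of rotation-based nulls.  P-values
are two-sided add-one, `p = (1 + #{|s_perm| >= |s_obs|}) / (n_perm + 1)`,
with 10,000 permutations by default.  Per-gene uncertainty comes from
bootstrap resampling of regions (default 1,000 resamples); each refit
component's sign is aligned to the original via the correlation of its
scores with the original scores on the resampled regions, the SE is the
resample SD, Z = w/SE with normal-tail p and BH-FDR q.  Signed gene sets
(positive-with-development, negative-with-aging) are selected at FDR
0.005.

## Genetics

Variant QC removes SNPs with call rate < 95%, MAF < 0.5% or imputation
INFO < 0.8.  LD clumping is greedy by ascending p (ties by position):
retain the index SNP, drop unretained SNPs within 250 kb with r^2 >= 0.1
(complete-case Pearson r^2 of dosages); the result is invariant to input
order.  PRS follows clump -> threshold -> score over the 100-threshold
grid 0.005..0.5 (step 0.005), averaging the per-threshold scores; a
`--include-p1` style option appends threshold 1.0.  Missing dosages are
imputed as twice the effect-allele frequency; weight files are aligned to
the panel's effect allele with sign flips, and strand-ambiguous (A/T,
C/G) SNPs are dropped.  The association scan is per-SNP OLS of the
phenotype on dosage plus covariates, implemented by projecting the
covariates out of phenotype and dosages once (Frisch-Waugh), with
genomic-control lambda = median(t^2)/0.4549 and a genome-wide significant
set (p < 5e-8) reduced by the same clumping rule.

## Synthetic data: what it emulates, and what it does not

The cohort generator produces an adult design (ages 44-82, ~90% single
scans, ~10% with a 4-6 y follow-up, emulating a 36,914/4,007
baseline/follow-up structure) and an adolescent design (ages ~13.5-23,
2-3 scans, 2-3.5 y gaps).  Volumes follow the quadratic trajectory model
above with per-ROI base volumes spanning the range of bilateral DK
parcels; defaults (fractions of base volume) are: random-intercept SD
0.10, random-slope SD 0.0015/y with intercept-slope correlation -0.2,
residual SD 0.025, ICV-attributable SD 0.12, annual decline 0.4%/y with
mild acceleration.  These are plausible placeholders, not values
calibrated to any published variance components.  Two planted aging
patterns differ by an intercept offset (in units of the analytic
cross-sectional baseline-volume SD, which includes ICV/age/covariate
variance — the population-SD convention for effect sizes) and a slope
offset (in units of the slope SD).  The mirrored cohort pair plants
opposite ROI rankings of annual change; the planted between-ROI spread is
wide enough that the ranking stays resolvable at the desk-scale cohort
sizes used here (a few hundred two-scan subjects), standing in for the
separation a full-scale cohort affords.  Baselines of the synthetic
adolescent cohort are staggered over 13.5-19.5 y rather than fixed at
enrollment waves, so the age-15 evaluation point lies inside (or within
the 1 y tolerance of) the midpoint-age support.

Expression matrices are Gaussian-process draws on the sphere of cortical
centroids (squared-exponential kernel in great-circle distance), with a
chosen subset of genes mixed with the target map at an exact in-sample
correlation.  Genotypes come from thresholded latent Gaussians following
an AR(1) within LD blocks; note the thresholding attenuates dosage LD
relative to the latent correlation, so `within_block_r` bounds rather
than equals the realized dosage r.  All generators derive child streams
from one global `SeedSequence`, so identical seeds give bit-identical
outputs.

None of this emulates segmentation error structure, scanner/site batch
effects beyond an additive term, population stratification, realistic
minor-allele spectra, or donor-level expression variability.  Passing
recovery and calibration benchmarks therefore shows the estimators are
correct and well calibrated under the stated generative model, not that
the pipeline is robust to the artifacts of real cohort data.

## Problem sizes of the validation runs

The validation suite and the reproduction script use: pattern recovery at
n = 2,000 subjects x 40 ROIs; deviation/phenotype recovery at n = 1,000
with 30% two-visit subjects; spin calibration over 500 runs x 200
permutations on 66 cortical parcels; scan calibration on 5,000 null SNPs
x 2,000 subjects plus 100 power replicates; mirroring recovery over 100
replicate cohort pairs (350 development / 250 aging subjects).  These
sizes were chosen as the smallest at which the corresponding statistical
claims are stable, and are stated here so results can be read at the
scale they were computed.

## Known limitations

- With ~90% singleton subjects the random slope is weakly identified;
  per-subject deviations then lean on pooling (the ICC is reported so the
  degree of pooling is visible).
- The rate curves absorb random effects in two stages rather than
  jointly; this is an approximation to a full additive mixed model.
- The spin null treats parcels as points (centroids), ignoring parcel
  area and boundary adjacency.
- Bootstrap gene p-values use the normal tail; genes with tiny SEs can
  reach extreme nominal significance.
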