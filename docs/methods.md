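# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `morphonorm`.

## Normative models and deviation scores

A normative model for a regional morphometric measure y is a sex-specific
regression of y on age and one global covariate, fitted in a healthy
reference sample. The deviation score of a subject is
z = (y − ŷ)/RMSE_m, with RMSE_m the *training-subset* RMSE stored in the
pretrained bundle. We fix RMSE_m to the training RMSE (rather than a
cross-validated RMSE) because it is a property of the shipped model,
independent of fold seeds; a useful corollary is that z-scores computed on
the training data themselves have mean 0 and population SD 1 exactly
(intercept-bearing least squares), which the tests verify to numerical
precision.

Global covariates are paired by measure family: mean cortical thickness for
regional thickness, total cortical surface area for regional area, and
intracranial volume for subcortical volume. New data are centred with the
bundle's stored training means; the subject's own global value is used at
prediction time (covariates are part of the model, matching the deployment
path of a pretrained-model service).

## Fractional polynomials and the RA2 closed test

The age term is selected from the canonical fractional-polynomial family
with powers P = {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 ≡ ln; repeated (p, p) ≡
z^p, z^p ln z): 8 FP1 and 36 FP2 candidates, all fitted by exact least
squares on the transformed basis. Form selection is the RA2 closed test at
α = 0.05 (conventional default): best FP2 vs null at 4 df, vs linear at
3 df, vs best FP1 at 2 df, each a χ² test on the Gaussian deviance
difference, stopping at the first non-significant step. Age is
force-retained (a normative model without age is meaningless, so step one
can only demote age to linear, never drop it); the global covariate is
restricted to a 1-df omit-vs-linear test in the optimised model. With
several covariates the selection cycles in order of decreasing initial
significance until a full cycle leaves all forms unchanged (at most 5
cycles; non-convergence returns the last forms with a warning).

Numerical choices:

* Deviance is D = n·ln(2π·rss/n) + n; only differences are ever used, and a
  test asserts invariance to the additive constant.
* Ties in the exhaustive search (within a 1e-8 relative band) break toward
  simpler powers: smaller Σ|p − 1|, then lexicographic.
* Transform domain: for a raw covariate with min(x) ≤ 0 the shift is
  −min(x) plus half the smallest positive gap between order statistics; the
  scale is a power of ten keeping the working range in [0.1, 100]. For the
  *centred age* inside a pretrained bundle the transform is instead anchored
  to the modelled age domain so that z = (age − mean + shift)/10 spans
  [1, ~9.7] over ages 3–90. Anchoring matters: a transform that lets z
  approach 0 makes negative powers explode at the young edge of the domain,
  which we observed to destroy extrapolation and longitudinal z stability
  before fixing the anchor.
* Rank-deficient designs raise immediately; there is no silent
  pseudo-inverse fallback.

## Benchmark algorithms

All comparison models sit behind one fit/predict contract:

* **OLSR** — exact least squares with intercept.
* **BLR** — conjugate Gaussian-prior linear regression. With fixed
  precisions the posterior mean is the ridge solution with penalty
  prior/noise (intercept unpenalised via centring); with precisions unset
  they are evidence-maximised (scikit-learn `BayesianRidge`). The vague- and
  dogmatic-prior limits (→ OLSR, → 0) are tested.
* **GPR** — exact dense RBF-kernel regression on standardised inputs.
  The inverse width is γ = 1/(2·q_med) with q_med the median squared
  pairwise distance over at most 5000 pairs — the midpoint of the usual
  0.1–0.9 quantile heuristic. Standardisation precedes the distance
  computation so mixed-scale covariate sets (years vs mm³) are handled.
  The jitter default is 1e-6; a singular kernel raises with instructions.
  Exact interpolation in the noise → 0 limit holds for narrow kernels; at
  smooth auto-widths the RBF Gram matrix is numerically rank-deficient in
  float64, so interpolation is verified with an explicit narrow width.
* **LMS** — simplified Box-Cox Cole-Green model: the outcome is BCCG with
  median μ(age) (polynomial basis, 5 coefficients), log σ(age) (3
  coefficients) and constant ν, fitted by BFGS from a moment-based start
  (μ from least squares on the basis, σ from the relative residual SD,
  ν from 1). The positivity-truncation correction is omitted, as is
  standard for small σ. Only age is accommodated, and the point prediction
  is the fitted median. ν = 1 reduces the model to a Gaussian with mean μ
  and SD μσ, which the tests exploit as an oracle.
* **external** — an adapter that registers any pre-fitted predictor (e.g.
  toolkit-based warped or hierarchical Bayesian regressions, which this
  package deliberately does not re-implement) into the same benchmark.

## Preparation pipeline

Sex-specific subsamples are split 80/20 by stratified randomisation on
site × age bin (the nine bins below); per-stratum train counts are
round(0.8·n_s), singletons go to train with a warning, and the assignment
depends only on the seed and subject identities, never input row order.
Extreme values are removed per measure using two-sided Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] under the type-7 (linear interpolation)
quantile convention — one pinned convention is required for exact
reproducibility. Removal is per measure, not per subject, because models
are fitted independently per measure. Centring constants are computed on
the training subset only and applied to the test subset and to any new
data; independent per-subset centring would make a pretrained model
inapplicable to new subjects.

Age bins are right-closed decades (3,10], (10,20], …, (80,90]; ages outside
[3, 90] get an explicit out-of-range label.

## Evaluation harness

Five-fold cross-validation with shuffled, seeded folds (sizes within one);
metrics are MAE (primary), RMSE, explained variance 1 − var(e)/var(y), and
per-fold CPU time via `time.process_time` (reported, never used in
selection — it is hardware-dependent). The covariate search evaluates nine
combinations — age alone; age plus vendor, FreeSurfer version, Euler
number, all three; age plus the global covariate linear or FP-eligible; and
the two global forms plus all acquisition covariates — scoring each by CV
MAE. Significance of an improvement over age-only uses a paired two-sided
Wilcoxon signed-rank on fold-level MAEs concatenated across measures
(5 fold pairs from a single measure cannot reach p < 0.05 by signed rank,
so the search is normally run over a measure list), with BH-FDR across
combinations at q = 0.05. Among significant sets, sets statistically
indistinguishable from the numerically best one (paired Wilcoxon p > 0.05)
count as tied, and ties resolve by complexity (token count, with an
FP-eligible global costing more than a linear one) then MAE — variables are
only retained when they significantly improve performance, which keeps the
winner stable against ~0.1% MAE jitter. Cross-algorithm comparison
concatenates per-measure metric vectors and applies paired Wilcoxon tests
per algorithm pair and metric with BH correction across all tests; the
Wilcoxon choice (the test statistic is not specified by convention) is
robust to the skewed MAE distributions across regions.

## Sensitivity analyses

Sample-size curves draw seeded subsets without replacement over a grid
(200–15000 in steps of 200 by default, 75 sizes) and record 5F-CV MAE/RMSE
per size. The plateau is defined operationally as the smallest size from
which the measure-averaged MAE stays within a 1% relative band around the
asymptote (mean of the three largest sizes); the band is configurable since
any plateau definition is a convention.

The age-bin analysis freezes each pretrained model's functional form,
re-estimates its coefficients by 5F-CV inside each of the nine bins (per
measure, after the same per-measure Tukey filter the preparation stage
applies; bins under 50 usable subjects are excluded with a warning), and
correlates the per-bin region-wise MAE/RMSE vectors with the full-sample
vectors (Pearson). A Kolmogorov-Smirnov normality check on the standardised
paired differences accompanies the correlations as a descriptive
diagnostic; it is reported, not acted on.

## Downstream validation

Diagnostic classification uses a linear-kernel SVC (C = 1, decision-function
values) with per-training-fold standardisation inside stratified 5-fold CV
repeated (100 by default), scored by held-out AUC. Symptom prediction uses
ridge (penalty 1.0) on the leading 10 principal components — fitted
strictly inside training folds and scaled to unit training variance so the
penalty acts evenly — with a warning when 10 components explain under 90%
of the variance (the two requirements cannot both bind in general; the
component count is fixed and the tension surfaced). Permutation inference
shuffles labels (or symptom scores) with a seeded generator, reuses the
statistic's own seed so fold structure is constant across permutations, and
reports p = (1 + #{null at least as extreme})/(n_perm + 1) — one-sided for
AUC-above-chance, two-sided (absolute deviation from the null mean) for
paired Δ statistics, which share one permutation across both feature sets.

## The synthetic cohort generator

The generator emulates the statistical structure of pooled multisite
lifespan cohorts. Per measure and sex: a ground-truth age trajectory built
from 1–2 FP powers (drawn from P, or overridden explicitly), scaled so the
age effect spans a family-typical fraction of the baseline level (35% for
thickness around 2.6 mm, 25% for area around 1600 mm², 30% for subcortical
volume around 4000 mm³); linear coupling to the age-standardised residual
of the paired global measure — the global measures have their own age
trajectories, so coupling is confounded with age and the covariate search
is non-trivial; additive per-site offsets (sum-to-zero) and multiplicative
site scale jitter; heteroscedastic noise with per-measure SD log-uniform
over [1%, 10%] of the level (a decade of spread, which is what makes the
age-bin correlation analysis informative — between-region noise
heterogeneity dominates bin-level jitter). Ages come from a
piecewise-uniform mixture with a child/adolescent bump (45% of subjects on
ages 3–25) over a 3–90 range, mimicking uneven enrolment; row order is
shuffled so it carries no age information. Euler numbers are negative
Poisson draws whose magnitude decays with age (worse surface quality in the
young). Outliers (1% by default, at most 5%) are displaced by 4–8 IQRs and
floored at 5% of the baseline level, since morphometry is physically
positive. Noise splits into a stable per-subject trait (80% of variance by
default) and scan-specific noise; follow-up visits advance each subject
along their own trajectory, keep the trait, and redraw the scan noise —
this is what makes subjects track their own centile, with truncated-normal
intervals (resampled if non-positive, floored at 0.5 y; 2.35 y and 1.76 y
mean intervals mirror typical rescan designs). Case-control cohorts shift
affected measures by a configurable multiple of that measure's noise SD and
derive symptom scores as a linear function of the true standardised shifts
plus noise, so closed-form AUCs (e.g. Φ(1/√2) for a 1-SD shift) are
available as oracles.

What the generator does **not** emulate: realistic between-region
covariance beyond the shared global coupling, scanner physics or image
artefacts, non-Gaussian residual shapes, cohort-specific age × site
confounding, and attrition. Passing tests therefore demonstrate that the
estimation machinery recovers the structure it models — not that real
multisite data satisfy that structure.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at sizes
chosen to make the statistical properties assertable while keeping a
single-CPU run comfortable: 2000 subjects per sex with all 150 measures for
the age-bin robustness study, n = 5000 × 100 replicates for form recovery,
900 per sex × 3 measures for the covariate search, 300 per sex for
longitudinal stability, and 200 null datasets at 200 permutations each for
type-I calibration. These sizes are the package's study conditions; the
grid constants (75 sizes, nine bins, 80/20 split) are fixed by design.

## Known limitations

* FP degree is capped at 2 and the Gaussian likelihood is assumed;
  heteroscedastic or skewed residuals are handled only by the separate LMS
  model, and no warped-likelihood or hierarchical Bayesian variants are
  included (they plug in via the external adapter).
* Site enters the synthetic truth but not the normative model; ComBat-style
  harmonisation is an interface hook (the pipeline accepts an externally
  harmonised table), not an implementation.
* z-scores assume the new subject's covariates lie inside the modelled age
  domain [3, 90]; extrapolation beyond it is refused by the basis domain
  check rather than silently extended.
* The simplified LMS fixes ν constant and uses plain polynomial bases;
  full GAMLSS-style penalised smoothing is out of scope.
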