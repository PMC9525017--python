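# Methods

This note documents the models, conventions and design decisions behind
`csvd_brainage`, in the order the pipeline runs them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Synthetic cohorts

### Generative model

The simulator emulates the post-imaging tabular stage of a two-cohort
brain-age study.

**Atlas.** A composite parcellation of cortical, subcortical and
cerebellar regions (default 400/14/28 = 442), cortical parcels cycling
through the seven canonical functional networks. Each region contributes
`voxels_per_region` voxel-level GMV feature columns (default 10 — enough
to preserve multi-feature structure per region while keeping regional
models desk-scale).

**Training cohort.** Ages uniform on 18–92 y (only the range of such
training sets is generally reported; uniform maximises support for model
fitting and is an assumption, not a claim about any real cohort). Voxel
GMV in region r:

```
g_irj = mu_rj − beta_r · age_i − q · age_i² + eps,   eps ~ N(0, sigma_g²)
```

Region baselines `mu_r` ~ N(550, 40²) with per-voxel offsets N(0, 10²),
aging slopes `beta_r` uniform on 0.8–2.5 units/year, optional quadratic
term q (default 0), noise `sigma_g` default 25 (arbitrary volume units).
Region parameters derive from a dedicated stream of the config seed, so
training and application cohorts share the same regional aging model; an
optional `cohort_seed` redraws the subjects while keeping that model fixed
(replicate designs).

**Application cohort.** Ages uniform on `app_age_range` (default 50–92),
plus covariates with community-cohort-like values: education ~ N(7, 5²) y
(mildly age-declining), EFC ~ N(0.545, 0.023²), TIV ~ N(1.31, 0.12²)
litres, and Bernoulli vascular risk flags (hypertension 0.33, diabetes
0.14, dyslipidemia 0.06, smoking 0.15), their log-odds shifted by latent
severity and age.

**CSVD status is not a label column.** A latent severity s ~ N(0,1)
couples the three marker generators — WMH volume lognormal (location
shifted by age and severity, median WMH/TIV near 0.7·10⁻³), lacune and CMB
counts Poisson with severity- and age-shifted log rates. The CSVD marker
rule itself (Section 3) is applied to the generated markers; subjects it
flags receive GMV computed at an *effective age* `age + delta_r · L_i` in
the designated affected regions, where `L_i ~ Gamma(k, 1/k)` (mean 1,
default shape k = 4) gives per-subject severity variation. Downstream
classification therefore reconstructs the planted groups by exercising the
classifier, and the mean extra aging in region r among CSVD subjects is
exactly `delta_r`.

**Cognition.** Each score is linear in covariates, in the per-subject true
extra-aging years of designated mediator regions (coefficients b, points
per year), and in CSVD status itself (direct effect c′), plus Gaussian
noise. The `GroundTruth` record carries everything needed for recovery
checks: flags, per-subject extra aging, delta, b, c′, and derived true
a·b, c and proportion mediated.

### What the generator does and does not emulate

It reproduces the *structure* the analysis assumes: monotone GMV decline
with age, marker distributions that support a median-split rule,
confounding of markers and cognition by age and covariates, and a planted
mediation pathway. It does not attempt spatial correlation between
regions, scanner/site effects, non-Gaussian GMV noise, or the numerical
summary statistics of any real cohort. Passing tests therefore certify
the estimators and their calibration, not claims about real data.

## 2. Brain-age models

Support-vector regression with the RBF kernel, one model per scope: the
global model uses all region-mean GMV columns; each regional model uses
only that region's voxel columns. Hyperparameters C and gamma are selected
from the seven-value grids {0.001, 0.01, 0.1, 1, 10, 100, 1000} by grid
search minimising mean absolute error in an inner 5-fold CV; an outer
5-fold loop reports out-of-fold MAE, R² and Pearson r (pooled metrics on
concatenated out-of-fold predictions). The final model is refit on the
whole training set with parameters chosen by a 5-fold CV over all of it —
a single whole-set selection rather than averaging per-fold winners.

Numerical conventions:

* **Feature scaling**: z-scoring inside the estimation pipeline with
  training-fold statistics only (RBF kernels need commensurate scales).
  Constant columns are warned about and guarded (scale 1).
* **Epsilon** of the insensitive loss: 0.1 y (library convention),
  recorded in `ModelSpec`.
* **Tie-breaking**: grid candidates are enumerated in ascending (C, gamma)
  order and the first best wins — smallest C, then smallest gamma.
* **Fold assignment**: shuffled once per run seed, stratified by age
  decile (falling back to coarser bins, then a plain shuffled split, when
  strata are too small); constant targets fall back to unstratified folds
  and R² is reported as NaN with a warning.
* **Solver cap**: `max_iter` = 2·10⁶ bounds pathological large-C fits.

BAG = predicted − chronological age, per scope. No post-hoc age-bias
regression is applied to BAG at prediction time; the group analysis
instead includes age and age² among the nuisance covariates, which adjusts
the well-known regression-to-the-mean bias of brain-age predictions where
it matters.

## 3. CSVD classification

`wmh_ratio = WMH volume / TIV` (units reconciled; ml and litre tags
accepted). The rule: ratio at or above the empirical 50th percentile of
the analysed cohort AND at least one lacune or at least one CMB. The
percentile uses the median-unbiased quantile convention with the
"at or above" comparison; both are recorded in the output provenance,
since no interpolation rule is canonical for this split. The threshold is
computed on the cohort being analysed. Classification is invariant to
subject order and common rescaling of ratios, and every flagged subject is
audited against both conjuncts at run time.

## 4. Group comparison

ANCOVA realised as OLS of the outcome on the CSVD indicator plus
covariates (age, age², sex, education years, EFC, TIV, four risk flags),
with the two-sided single-df t test of the indicator. Effect size is
partial η² = SS_group/(SS_group + SS_residual) with SS_group the partial
(last-entry) sum of squares; with a single focal term this coincides with
Type II/III and satisfies η² = t²/(t² + df_resid), which the tests verify
to 1e-10. If the covariates fit the outcome perfectly both sums of
squares are numerical dust and η² is reported as 0. Regional tests use
the Bonferroni threshold α/K for K regions analysed; the single global
test is uncorrected. Rank-deficient designs are rejected with the first
collinear column named.

## 5. Mediation

Three least-squares regressions, all including the same confounders
(age, age², sex, education, EFC, TIV — risk flags deliberately excluded,
matching the group-comparison-versus-mediation covariate split):

* covariates are *included as regressors*, not pre-residualised; the
  Frisch–Waugh–Lovell theorem makes the point estimates identical either
  way (verified in tests), and inclusion keeps case-resampling bootstrap
  valid;
* covariate columns are z-scored inside the design builder — with an
  intercept present this leaves every path coefficient unchanged and
  conditions the normal equations well even with an age² column, which is
  what lets the identity c = c′ + a·b hold to 1e-10 (asserted at fit
  time on every model);
* the bootstrap resamples whole rows; resamples with a constant exposure
  or mediator are redrawn (capped, then an error);
* BCa intervals: bias constant z₀ = Φ⁻¹(#{θ* < θ̂}/B) (clamped to
  (1/2B, 1−1/2B) with a warning when the bootstrap lies entirely on one
  side), acceleration â from the jackknife skewness formula; with
  z₀ = â = 0 the interval reduces exactly to the percentile interval.
  `accelerated=False` restores plain bias-corrected intervals;
* p-values invert the interval: the smallest α at which the BCa interval
  excludes zero, two-sided, floored at 1/B;
* all bootstrap regressions are solved as batched normal equations
  (chunked), which keeps B = 10 000 at cohort scale in the seconds range;
* proportion mediated = 100·a·b/c, flagged undefined when |c| < 1e-8 and
  reported raw (not truncated) outside [0, 100]. A BCa interval for the
  proportion itself is computed from the per-resample ratio whenever every
  resampled total effect keeps the sign of ĉ — when c* straddles zero the
  ratio distribution is unstable and no interval is reported;
* a screened (region × outcome) pair is declared significant when all of
  p_a, p_b, p_ab < α (configurable via `require_paths`); an optional
  family-wise column applies α divided by the number of screened models.
  Default B = 10 000; the test suite uses B = 1000–2000 with
  correspondingly widened Monte-Carlo bands.

## 6. Pipeline

One master seed expands deterministically into per-stage seeds
(simulation, model fitting, mediation), so partial reruns and full reruns
are bit-identical; every artifact directory carries a config hash that
covers the analytic content only (not the output path). A rerun in a
directory whose BAG table was written under the same hash skips the
training stage and resumes from the cached table, reading floats with
round-trip precision so downstream outputs stay identical. Tables travel
as TSV with JSON sidecar schemas; reading validates against the sidecar
and reports all violations at once; TIV in millilitres (column name or
unit tag) is converted to litres on read.

## 7. Recovery experiment design

The acceptance suite plants 8 y of extra aging in 5 of 40 regions and
asks that exactly those regions pass Bonferroni in ≥95% of 20 seeded
replicates, and that the planted mediator's true proportion mediated falls
inside its 95% BCa interval in ≥90%. Three identifiability considerations
shaped the experiment's conditions, and they generalise to real studies:

* **Training-age support.** An RBF-SVR saturates outside the support of
  its training ages, so effective ages (age + extra aging) beyond the
  training maximum compress the estimated BAG exactly in the most affected
  subjects — measured attenuation of the BAG-versus-true-extra-aging slope
  from ≈0.9 to ≈0.26 when application ages run to the training maximum.
  The experiment caps application ages at 80 y so effective ages stay
  inside the 18–92 y training range.
* **Mediator measurement error.** Path b is estimated from within-cohort
  variance of the mediator; BAG noise in the (large) non-CSVD group enters
  the denominator and attenuates b. The low-noise condition therefore uses
  sigma_g = 4 and a right-skewed severity multiplier (Gamma shape 2), so
  extra aging varies substantially within the CSVD group relative to BAG
  noise. Residual attenuation of a few percent remains and is absorbed by
  the bootstrap interval width.
* **Age-balanced groups.** With age-coupled markers the CSVD group is
  older, and any model age-bias not captured by the age and age²
  covariates surfaces as false positives in null regions once noise is
  small. The recovery experiment drives the markers by latent severity
  only, balancing the groups' ages and isolating the planted effect; the
  age-coupled defaults remain in place everywhere else.

Calibration experiments fix their Monte-Carlo bands in advance from
binomial standard errors: the indirect-effect test's type-I error over 500
replicates (B = 1000) must lie within 0.05 ± 2.576·SE, and the null
regional screen's family-wise error over 60 replicates within nominal +
2·SE.

## 8. Problem sizes

The test suite runs cohorts of 40–300 subjects, atlases of 10–40 regions,
and bootstrap sizes of 200–2000; the acceptance script uses 260 training
and 250 application subjects over 40 regions with B = 2000, full
seven-value grids for the global model and a reduced C grid for regional
models. These sizes were chosen to make the whole suite a coffee-break
run on a single CPU while keeping every statistical check at sensible
power.

## 9. Known limitations

* No spatial correlation between regions; each region's noise is
  independent, so family-wise behaviour over correlated real regions may
  differ.
* The mediation model is single-level and makes no causal-identification
  claims beyond the standard regression assumptions; no sensitivity
  analysis for unmeasured confounding is provided.
* The proportion mediated is a ratio estimator and is unstable when the
  total effect is near zero; the package flags rather than fixes this.
* BCa intervals are not guaranteed to contain the point estimate in
  principle; no such invariant is asserted.
* Brain-age models here are kernel regressions on simulated GMV; absolute
  MAE/R² values depend entirely on the simulated noise level and should
  not be read as benchmarks for real MRI features.
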