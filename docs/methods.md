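# Methods

This note records the statistical models implemented in `repeatrisk`,
the conventions chosen where more than one reasonable convention
exists, what the synthetic-data generator does and does not emulate,
and the numerical choices that make the package deterministic.

## Genotype representation

Each subject carries two *HTT* CAG repeat counts, stored ordered as
A1 ≤ A2.  Counts are classified into ranges
*a* 7–12, *b* 13–(s−1), *c* s–26, *d* 27–35, *e* 36–39, where the
*b*/*c* boundary *s* defaults to 21 and may be moved over 14–26; the
five bins partition [7, 39] for every admissible *s*.  Counts ≥ 40 lie
in the fully penetrant HD range, which the modelled population does not
contain; they are flagged `hd_full` and excluded from association
screens with a logged warning rather than being silently folded into
*e*.  Genotype-combination labels are the two range letters in
alphabetical (equivalently, nondecreasing-length) order; 15 labels are
possible, of which cohorts without *e*/*e* pairs realize at most 12–13.

Fragment-size calibration (toy scale) maps capillary-electrophoresis
fragment sizes to repeat counts by ordinary least squares on a table of
reference fragments with known repeat numbers, with half-up rounding.
The linear form is the minimal choice given the fixed 3-bp repeat unit.
Calls above 35 repeats are reported `confirmed` only with a concordant
replicate measurement, otherwise `unconfirmed`; sizes mapping outside a
plausible repeat domain of [6, 60] are rejected.

## Odds-ratio screen

For one case group, one stratum and one combination, carriers are
subjects whose label equals the combination and noncarriers are all
other subjects of the same roster (carrier-vs-rest).  The screen emits
a combination only when it has at least `min_count` (default 5)
carriers in both the case and the control group; the noncarrier cells
are unconstrained.  The OR is the cross-product ratio with a 95 % Wald
interval on the log scale; when any cell is zero, 0.5 is added to all
four cells (Haldane–Anscombe) before both estimate and interval.
Significance is the two-sided Fisher exact test (sum of hypergeometric
probabilities not exceeding the observed table's); q-values are
Benjamini–Hochberg within one case-group × stratum screen.  The
carrier-vs-rest construction is a documented convention: a 2×2 table
requires a reference set and carrier-vs-rest is the standard choice for
genotype-frequency screens.

The omnibus combination-by-status association uses the exact
(probability-ordering) test on the full K×2 table.  Since closed-form
enumeration is impractical beyond 2×2, the p-value is estimated by
Monte Carlo over tables drawn with the observed margins (Patefield's
algorithm, 2000 seeded draws, +1 numerator/denominator correction); the
2×2 case falls back to the exact test.

Age stratification splits at 48 years with the older stratum inclusive
(age ≥ 48).  The split-point scan rebuilds the range scheme for each
boundary in 19–23 (configurable within 14–26) and recomputes the *bb*
and *bc* odds ratios; the summary statistic is the signed difference
log OR(*bc*) − log OR(*bb*) per split.

Mean repeat-count comparisons between groups use one-way ANOVA, or
ANCOVA with age and sex covariates, with the group-factor F test taken
from a type-II decomposition.

## Two-allele logistic risk model

Case status is modelled as Bernoulli with

  logit P(case) = β₀ + β₁x₁ + β₂x₂ + β₃x₁² + β₄x₂² + β₅x₁x₂,

where x₁ = A1 − mean(A1) and x₂ = A2 − mean(A2).  Centering before
squaring bounds the collinearity of the polynomial terms and makes the
intercept interpretable at the allele means; it changes raw-basis
coefficients but not the fitted probabilities.  The design (intercept
first, then the five terms in the order listed) is orthonormalized by
modified Gram-Schmidt; columns are unit-Euclidean-norm, so orthonormal
coefficients scale with √n.  The recorded transform T is
lower-triangular with Q = X Tᵀ, and raw-basis coefficients are
recovered as β = Tᵀγ.  Rank deficiency (e.g. a constant allele) raises
an error naming the first dependent column.

Fitting is maximum likelihood by iteratively reweighted least squares
(statsmodels GLM, binomial family) with a coefficient-change tolerance
of 1e-10 and at most 100 iterations; non-convergence or diverging
coefficient norms (a complete-separation symptom) flag the fit rather
than raising.  Wald z-tests give per-term p-values.

Age-stratified fits are produced for the younger (< 48) and older
(≥ 48) subsamples.  The pooled model adds a two-level age factor and,
by default, its interactions with A1, A2, A2² and A1·A2 — the
interaction set of scientific interest here; an optional full set
(age × all five terms) makes the pooled model span the two stratified
fits exactly, which the tests exploit as a consistency check.

The relative-risk surface evaluates the fitted model on the integer
(A1, A2) grid and divides the predicted case probability by the case
proportion of the fitted subsample.  Because an intercept-bearing
logistic fit reproduces the sample case fraction as the mean of its
fitted values, the frequency-weighted mean relative risk over observed
cells equals 1 (to numerical precision) — a built-in normalization
check.  With extrapolation enabled the grid covers the full observed
rectangle with a1 ≤ a2 and unobserved cells are flagged.

## Phenotype regressions

A1_orth is the residual of the least-squares regression of A1 on A2
(with intercept); it is exactly uncorrelated with A2 in-sample, and the
(A1_orth, A2) pair spans the same space as (A1, A2), so predictions are
unchanged while coefficients become interpretable.

Standardization convention: the outcome (linear models) and all
continuous predictors are z-scored; binary predictors are 0/1;
categorical covariates are dummy-coded; interaction columns are
products of the standardized components (not standardized products).
Age enters volumetric models continuously and clinical models as a
two-level factor split at 50 years.  Linear models report adjusted R²;
binary outcomes use logistic regression with Nagelkerke's pseudo-R².
FDR is applied per term across the outcome family, matching per-column
adjustment of a results table.

The normative-deviation transform fits a linear model of the outcome
on age, sex, eICV and coil type using reference subjects only
(≥ 50 required) and reports 100 × (measured − predicted)/predicted for
all subjects; non-positive predictions are flagged NaN.  In-sample,
the mean deviation is near zero but not exactly zero because the ratio
transform is nonlinear in the residuals.

The A2-split profile refits the phenotype model within the low
(A2 < s) and high (A2 ≥ s) subsamples for successive split positions s
and records the A1_orth coefficient; subsamples below 30 complete
cases are skipped with a warning.  An A2-conditional effect appears as
a high-vs-low gap that peaks at the true threshold.

Configurable item-subset scores (summing a named subset of item
columns) support sub-score contrasts such as anhedonia-related
inventory items; the item list is configuration because no canonical
list exists.

## Synthetic-data generator

The generator is a pure function of (config, seed); all randomness
flows through one `numpy` Generator.

*Allele marginal.*  A gamma density integrated over unit bins on 7–39,
truncated and renormalized, with the gamma parameters solved
numerically so the discrete distribution has exactly mean 18.4 and SD
3.2 — right-skewed, like population CAG distributions.  The exact
population pmf is not identifiable from summary moments, so this
marginal is a stand-in with matched low-order structure.

*Within-subject correlation.*  Allele pairs are drawn from a Gaussian
copula and sorted (A1 ≤ A2).  Sorting itself induces correlation
(≈ 0.46 at latent ρ = 0), so the latent ρ is calibrated by bisection on
a fixed 10⁵-draw pilot (common random numbers) until the post-sorting
Pearson r hits the target 0.36 ± 0.002; the achievable range is roughly
[−0.97, 0.995] and unreachable targets raise a configuration error.
Sorting unordered draws is the simplest mechanism consistent with "A1
is the lower count".

*Reduced-penetrance alleles.*  After sampling, A2 is overwritten with a
uniform draw from 36–39 in a Bernoulli-selected subset (default rate
1/500), keeping the carrier frequency interpretable per subject.

*Demographics.*  Default group sizes 2136 (MDD), 493 (ANX), 1566 (CON)
with group ages N(49.2, 14.1), N(37.7, 12.1), N(49.6, 13.8) truncated
to [17, 90] and female proportions 0.585/0.582/0.630 — the cohort
structure the analyses target.

*Planted effects.*  A planted logistic risk model (polynomial allele
terms with optional stratum restriction, a repeat-threshold log-odds
step, and/or a log-odds offset on a canonical combination label)
defines each candidate's case probability; candidates are accepted
into case groups with probability p and into controls with 1 − p until
the requested sizes are met, i.e. case-control sampling from the
planted population.  A combination-label offset makes the
carrier-vs-rest OR of that combination equal the planted value
exactly; a repeat-threshold step at 21 instead plants a contrast that
the split-point scan should localize, with the carrier-vs-rest OR
mildly attenuated (≈ 2.2 → ≈ 1.95) because some noncarrier
combinations (e.g. *cc*, *cd*) also sit above the threshold.
Phenotypes are linear in standardized components with residual noise
topping the variance up to ~1, so planted coefficients are recovered
as standardized betas; an optional A2-conditional A1_orth effect
creates threshold structure for the split profile.

*What passing tests do and do not show.*  Recovery on these cohorts
demonstrates that the estimators are unbiased and calibrated under the
generative assumptions (copula alleles, logistic risk, linear-Gaussian
phenotypes, complete data).  Real cohorts add genotyping error,
covariate-dependent missingness, population structure and selection
effects that the generator does not emulate; passing tests therefore
validate the machinery, not the biology.

## Problem sizes and numerical choices

Simulation experiments use sizes chosen to make sampling error small
relative to the tolerances they are checked against: odds-ratio
recovery averages 100 seeded cohorts of 1500 per arm (older stratum);
the null screen's type-I error uses 500 cohorts of 750 per arm;
split-point localization uses one 4000-per-arm cohort; the volumetric
recovery mirrors the target regression's n = 544 over 100 seeds; the
split-profile localization averages 5 cohorts of 1400.  Gram matrices
are checked to 1e-10, basis invariance to 1e-8, orthogonalization of
A1_orth to 1e-12, the surface normalization to 1e-6.  Monte-Carlo
omnibus p-values use 2000 draws with a fixed seed.  Ties in the
split-scan maximum are broken toward the smaller split by the argmax
convention.  Degenerate inputs (empty strata, one-label fits, constant
A2, all-zero tables) raise errors rather than returning quiet
nonsense.

## Known limitations

- The omnibus exact test is Monte-Carlo, so its p-values carry ≈ 1/√N
  resampling noise and a +1 correction floor.
- Wald intervals for the OR are first-order; exact conditional or
  mid-p intervals are out of scope.
- The pooled risk model's default interaction set is the restricted
  one; stratum-specific curvature in A1² is only representable with
  the full interaction set.
- The generator's allele marginal and copula are moment-matched
  stand-ins, not an estimate of any real population's pmf.
- Fragment calibration assumes an exactly linear size→repeat map and
  does not model stutter or peak-calling artefacts.
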