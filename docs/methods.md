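# Methods

## Design and model

A case-base study recruits from a defined population of size N through
two independent Bernoulli sampling schemes: a *case sample* taken with
probability γ among incident diseased subjects, and a *base sample*
taken with probability τ from everyone, diseased included. A subject
selected by both schemes is one recruited subject carrying both
membership flags; all analyses operate on distinct recruited subjects.

The population disease model is logistic, `logit P(D=1|x) = α + xβ`,
with `q = exp(α)` the disease odds at the reference profile x = 0 and β
a vector of log odds ratios. Conditional on recruitment the disease risk
is again logistic in the same covariates with intercept
`α* = α − log ρ`, where `ρ = τ/(γ + τ − γτ)` is the probability that a
recruited diseased subject belongs to the base sample. The recruited-data
likelihood factorizes into three parameter-orthogonal blocks — binomial
in γ (count n₁₁ of n₁), binomial in ρ (count n₁ of n_D), logistic in
(α*, β) — with zero cross second derivatives, which justifies treating
the three variance pieces as independent.

Estimation is therefore: an ordinary logistic fit of disease status on
the covariates over all recruited subjects (every subject once,
regardless of recruitment route); `ρ̂ = n₁/n_D`; and the intercept
correction `α̂ = α̂* + log ρ̂`, which is exact as a maximum-likelihood
composition, not an approximation.

### Variances

`var(ρ̂) = ρ̂(1−ρ̂)/n_D` (binomial); the logit-scale risk and log-RR
variances need `var(log ρ̂) = (1−ρ̂)/(n_D ρ̂)` by the delta method. For a
profile x (row vector aligned with the model columns):

- `var(logit p̂(x)) = z V zᵀ + var(log ρ̂)` with `z = (1, x)` and V the
  logistic-fit covariance of (α*, β);
- `var(log RR(x₁, x₀)) = h V hᵀ + c² var(log ρ̂)` with
  `h = [(1−p̂₁)−(1−p̂₀), (1−p̂₁)x₁ − (1−p̂₀)x₀]` and
  `c = (1−p̂₁)−(1−p̂₀)`, using `d log p / d logit p = 1 − p`.

The gradient h is validated in the test suite against central finite
differences of log RR with respect to (α*, β, log ρ) (6 significant
digits on randomized fits) and against a 2,000-resample nonparametric
bootstrap of a fixed dataset (within 10% relative error). Confidence
intervals are Wald intervals on the log/logit scale (z = 1.959964 at
95%), back-transformed; γ̂ = n₁₁/n₁ is a nuisance and never propagates.

### Degenerate cases

- `n₁ = 0`: ρ, α, risks and RRs are not estimable and requesting them
  raises `NotEstimableError`; odds ratios remain valid.
- `ρ̂ = 1` (everyone in the base sample): `var(log ρ̂) = 0` and every
  output coincides with a plain cohort logistic analysis, verified to
  1e−10 against a direct cohort fit.
- `n₁₁ = 0`: γ̂ is unavailable (NaN) with no effect on any risk output.
- Complete or quasi-complete separation: reported as `SeparationError`
  naming the diverging column (threshold |β̂| > 30); no penalized
  fallback is attempted.

## Comparators

- **Single-binary-exposure closed form (Sato).** With recruited diseased
  a₁/a₀ and non-diseased recruits b₁/b₀ by exposure, the saturated
  logistic MLE is `exp(α̂*) = a₀/b₀`, `exp(α̂* + β̂) = a₁/b₁`; the general
  formulas collapse to
  `var(log RR) = (1−p̂₁)²(1/a₁+1/b₁) + (1−p̂₀)²(1/a₀+1/b₀) + c²·var(log ρ̂)`.
  `sato_rr` implements this specialization and is tested to agree with
  the regression path to 1e−12 in point and variance.
- **Crude exposure-odds ratio (Miettinen).** Point estimate
  `(a₁/a₀)/(B₁/B₀)` with B the base-sample counts by exposure; it never
  uses the overlap counts. The original variance algebra is not
  reproduced here, so the shipped variance is a reconstruction: the
  delta-method form `1/a₁+1/a₀+1/B₁+1/B₀ − 2o₁/(a₁B₁) − 2o₂/(a₀B₀)`
  that accounts for the diseased-in-base overlap o appearing in both
  numerator and denominator counts. The plain reciprocal sum (which
  ignores the positive covariance and is conservative: empirical
  coverage ≈ 0.96 instead of 0.95 in the binary scenario) and a variance
  borrowed from the closed form remain available via `variance=`.
- **Duplication.** Diseased base-sample members are duplicated, the
  copies relabeled non-diseased, and a logistic model fitted to the
  expanded data; coefficients are read as log RRs. On census data with a
  saturated binary model this returns exactly the empirical log risk
  ratio. It is unbiased for a single binary exposure but less efficient
  than the model-based estimator, and biased for multi-level exposures.

In multi-exposure scenarios the two 2×2 comparators are applied per
non-reference profile against the reference profile, restricted to the
data from those two profiles (including ρ̂ re-estimated from that
subtable); this is the package's reading of "apply the single-exposure
method levelwise" and is documented here because other conventions (e.g.
a shared full-sample ρ̂) are defensible too.

## Synthetic data generator

`CovariateSpec` describes marginals (binary prevalence; categorical
level probabilities with level 0 as reference; continuous scipy
distributions), `Design` the encoding into model columns (dummy or
integer-score coding for categoricals, optional product columns) and the
joint distribution — the independence product by default, or an explicit
joint profile table for dependent covariates such as the
exposure-confounder scenario. `solve_baseline_odds` finds the intercept
matching a target marginal prevalence; `simulate_population` draws
covariates and Bernoulli disease; `draw_case_base_sample` applies the
two Bernoulli recruitment schemes with independent streams split from
one master seed (covariates / disease / case / base).

The generator emulates the idealized design: i.i.d. subjects, perfectly
classified disease status, exactly known sampling probabilities, no
measurement error, no time dimension and no loss to follow-up. Passing
tests therefore demonstrate the estimator's statistical properties under
its own assumptions — not robustness to misclassification, selection
bias beyond the modeled sampling, or time-varying exposure. Deliberate
misspecification is limited to the built-in variants (omitted
confounder, omitted interaction, saturated-vs-scored coding).

### Built-in scenarios

All share N = 100,000, γ = 0.05, τ = 0.005 unless noted; effect sizes
are ORs 2.5 (and 3 where a second exposure exists) with marginal disease
prevalence 0.1 — the standard settings whose reference summaries the
acceptance tests target. Scenario constants not fully specified in those
references are reconstructions, flagged in `notes`: the continuous
exposure is standard normal with per-unit log OR log 2.5; the
interaction scenario adds a product term with log OR log 2; the
confounder is binary with prevalence 0.4, disease log OR log 3 and
exposure prevalence 0.2/0.4 by stratum. Low-prevalence variants rerun
the binary scenario at prevalence 0.05 and 0.01.

One inconsistency in the reference constants is worth recording. For the
four-level exposure scenario (level probabilities 0.5/0.3/0.1/0.1,
adjacent-level OR 2.5, marginal prevalence 0.1), exact solving gives a
reference-level logit risk of −3.2799, while the reference tables list
−3.2708 — a value whose implied marginal prevalence is 0.10073. Their
remaining four-level constants are internally consistent with −3.2708,
so their intercept solve, not their table derivation, appears to have
been off. This package always solves exactly (residual below 1e−12) and
reports exact truths; consequently its four-level truths differ from the
listed ones by up to 0.009 on the logit scale, and its two-exposure
logit risks by about 1e−4. Simulation means shift by the same small
amounts.

## Monte-Carlo engines and problem sizes

With discrete covariates the whole study collapses onto per-profile
sufficient counts: profile totals are multinomial, diseased counts
binomial, and recruitment a chain of binomials (case; case∩base;
base-only; non-diseased base). The grouped logistic likelihood equals
the row-level one, so all replicates are fitted simultaneously by a
replicate-batched Newton solver (`_engine.batched_logistic`), giving
10,000-replicate studies in well under a second. The batched solver is
tested cell-by-cell against statsmodels on identical counts. A row-level
engine (`engine="subject"`) materializes each population and dataset —
required for continuous exposures, and used to cross-check the counts
engine statistically. Default study sizes follow the scenario
definitions (10,000 replicates); the test suite uses 100–2,000
replicates for cross-checks and the documented acceptance runs use
10,000 (binary scenario) and 2,000 (multi-level scenarios).

Replicates where a quantity is inestimable (n₁ = 0, empty or separated
cells) are excluded from that quantity's aggregation and counted in
`n_failed`; coverage denominators use the retained replicates. Every
cell carries a Monte-Carlo standard error (mean: s/√n; coverage:
binomial; variance: normal-theory s²√(2/(n−1)); CI length: s/√n of the
lengths).

## Numerical choices

- Baseline-odds root finding: Brent's method on the log-odds scale over
  [−40, 10] (the risk expectation is strictly monotone in the intercept,
  so the root is unique), xtol 1e−14, residual checked against 1e−12.
- Expectations over covariates: exact finite-support sums; 80-point
  Gauss–Hermite quadrature for normal covariates; otherwise Monte-Carlo
  with 1e6 fixed-seed draws.
- Logistic fits: statsmodels GLM/IRLS (tol 1e−12, ≤200 iterations)
  followed by Newton polishing to a parameter step below 1e−13, because
  deviance-based stopping leaves ~√tol slack in the parameters and the
  closed-form equivalences are asserted at 1e−12. Covariance is the
  inverse (observed = expected, canonical link) information at the
  polished optimum.
- Batched Newton: step damping at max-norm 10, singular-information and
  divergence (|β̂| > 30) replicates flagged rather than fitted.
- Duplicate covariate patterns are kept as individual Bernoulli rows in
  the user-facing path (the grouped engine is an equivalent
  reformulation, not an aggregation-with-ties policy).
- The reference profile is the all-zeros row; categorical dummies are
  coded against level 0; RR of the reference profile is set to exactly 1.

## The design-precision calculator

`plan(n_distinct, prevalence, diseased_fraction)` targets the recurring
design question: how many diseased subjects will the base sample
contain? Non-diseased subjects enter only through base sampling, so a
design expecting n₀ non-diseased recruits implies a base sample of about
n₀/(1−π) members and `expected_n1 = n₀ π/(1−π)` diseased ones at
prevalence π. The returned CI ratio `exp(2·1.96·√(1/n₁ + 1/n₀))` is the
expected upper/lower bound ratio of the 95% interval for the prevalence
odds estimated from the base sample — a scale-free summary of how
informative the design is about absolute risk; a warning flags designs
with expected n₁ < 1, for which risks and RRs are practically
inestimable.

## Known limitations

- Retrospective design only: no time-to-event structure, no case-cohort
  pseudo-likelihoods, no stratified or matched sampling, no
  finite-population corrections beyond the Bernoulli scheme itself.
- Wald intervals only (no profile-likelihood or score intervals); small
  n₁ makes the log-ρ̂ variance term, and hence the intervals, unstable.
- The Miettinen variance is a reconstruction calibrated against the
  binary-exposure reference summaries, not a transcription of the
  original algebra.
- Populations are materialized in memory at the 1e5 scale in the
  row-level path; there is no streaming mode.
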