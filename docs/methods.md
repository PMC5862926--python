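# Methods

## Hypotheses, priors, and what a Bayes factor is here

Every test in this package compares a point null against an alternative that
assigns the key parameter a default prior. The Bayes factor is the ratio of
marginal likelihoods, BF₁₀ = p(y | H₁)/p(y | H₀); BF₀₁ = 1/BF₁₀ is the same
evidence reported in the other direction, and the package always stores the
natural log so the reporting direction is a display choice.

### Effect-size prior (t-test)

δ ~ Cauchy(0, r). The Cauchy scale r is the prior interquartile range of the
standardized effect; the default r = √2/2 is stored exactly (0.707 is a
display rounding). One-sided hypotheses use the folded Cauchy — twice the
symmetric density on the hypothesized half-line, zero elsewhere — so that for
any symmetric two-sided prior BF₁₀ = ½(BF₊₀ + BF₋₀), an identity the test
suite asserts on random draws. The Cauchy makes the test information
consistent (two identical noise-free observations give infinite evidence),
and as r → 0 the alternative collapses onto the null, driving BF → 1.

### Correlation prior

ρ ~ stretched beta: a Beta(1/κ, 1/κ) rescaled to (−1, 1), density
∝ (1−ρ²)^(1/κ−1). κ = 1 is uniform; smaller κ concentrates on ρ = 0
(the prior sd is ≈ √(κ/2) for small κ, so BF → 1 as κ → 0 at rate O(κ)).
κ is restricted to (0, 2] so both beta shape parameters stay ≥ ½; at κ = 2
the density has integrable endpoint singularities, which the quadrature
handles because the likelihood vanishes at |ρ| = 1 for n ≥ 3.

### Likelihood for the sample correlation

The default "exact" likelihood is the small-sample density of the sample
correlation of a bivariate normal, proportional in ρ to

    (1−ρ²)^((n−1)/2) (1−ρr)^(−(n−3/2)) · ₂F₁(½, ½; n−½; (1+ρr)/2),

evaluated in log space with `scipy.special.hyp2f1`. The classical
approximation dropping the ₂F₁ factor is available as
`likelihood="jeffreys"`; for n = 46 the two agree to well under 2%. A sample
correlation of exactly ±1 returns an infinite log Bayes factor (information
consistency) rather than attempting quadrature.

### g-priors for linear models

For a response y with factorial predictors, the model is
y = μ1 + Σ_t X_t β_t + ε, ε ~ N(0, σ²I), with p(μ, σ²) ∝ 1/σ². A k-level
factor is coded as Z Q, where Z is the cell indicator and Q an orthonormal
basis of the sum-to-zero subspace (k−1 columns, from the eigendecomposition
of the centering matrix); interaction blocks are row-wise Kronecker products
of their components' blocks. Each term's standardized effects get
β_t | g_t ~ N(0, g_t σ² I) with g_t ~ inverse-gamma(½, r_t²/2) — the mixture
that makes implied effect sizes Cauchy(0, r_t). Defaults: r_fixed = 0.5,
r_random = 1.0. The random-participant scale is wider because subjects are
assumed a priori variable; these defaults reproduce the published values of
the reference analyses (e.g. the hair-colour BF of 11.97 and the singers
table) to within their stated integration error.

With this coding, a balanced two-group one-factor model with r_fixed = 0.5
is exactly the JZS t-test with Cauchy scale √2 · 0.5 = 0.707; the suite
asserts agreement to 10⁻³ in log BF. Two consequences of the standardized
parametrization are also asserted: affine rescaling y → ay + b leaves every
Bayes factor invariant, and adding a pure-noise factor is disfavored
(BF < 1) in ≥ 90% of null replicates.

Conditional on g = (g₁…g_p), everything else integrates analytically:

    BF(g) = |I_p + G^½ X'X G^½|^(−½) ·
            ( (ỹ'ỹ − ỹ'X G^½ (I_p + G^½X'XG^½)⁻¹ G^½X'ỹ) / ỹ'ỹ )^(−(N−1)/2)

where ỹ is the centered response and X the column-centered design —
centering implements the flat-prior integration of the intercept and
matters for unbalanced designs, where effect columns are not orthogonal to
the ones vector.

### The g integral

* p = 1 (one term): deterministic adaptive quadrature on u = log g, the
  integrand centered at its mode. The reported error percentage is the
  quadrature error estimate relative to the integral (in practice ~10⁻⁸%).
* p > 1: seeded importance sampling. The mode of the log-scale integrand is
  found by Nelder–Mead, the Hessian by finite differences, and samples are
  drawn from a multivariate normal in log g (a log-normal proposal) with
  covariance inflated by 1.44 to cover heavier-than-Gaussian tails.
  10 000 samples by default; the error percentage is 100 · sd(weights) /
  (√M · mean(weights)), the analogue of a coefficient of variation; results
  are bit-reproducible given (seed, mc_samples), and estimates with error
  above 15% carry a warning flag. Within an `run_anova` call, model i uses
  seed + i so models are independent but the whole table is reproducible.

## Numerical integration

All one-dimensional marginal integrals use one engine: an adaptive composite
Gauss–Legendre rule (nested 10/21-point panels, bisected until coarse and
fine estimates agree to 10⁻¹⁰ absolute / 10⁻⁸ relative), with the integrand
evaluated on whole abscissa arrays. Integrals over the real line are folded
through x = center + scale·tan(πu/2), centered at the maximum-likelihood
effect size so the posterior bulk is well resolved. The noncentral-t density
is zeroed where scipy returns NaN at astronomically large noncentralities
probed by the tail transform (the true value there is 0). Deterministic
results report an error percentage only when the estimate exceeds 10⁻⁶%.

Posterior summaries (median, equal-tailed 95% interval, density at the null
for Savage–Dickey ratios) invert the quadrature-based CDF with Brent's
method; one-sided posteriors are truncated and renormalized on their
half-line. The Savage–Dickey route (posterior/prior density ratio at the
null value) agrees with the marginal-likelihood route to 10⁻³ relative
everywhere tested — a genuine dual-route check, since the two computations
share only the likelihood.

Model-space arithmetic (posterior model probabilities, BF_M, inclusion
probabilities, rebasing onto a different base model) is done entirely in log
space with log-sum-exp; published tables reach 8×10³⁹ and survive unchanged.
A model with posterior probability 1 reports BF_M = +∞ rather than an error.

## Data handling

CSV input is read with stdlib `csv` parsing (RFC-4180 quoting) into typed
tables. Measurement levels are guessed: all-numeric columns with more than
10 distinct values are continuous, all-numeric otherwise ordinal, anything
else nominal — the threshold is a convention, overridable per column.
Decimal-comma columns are rejected outright instead of silently misparsed.
Missing values are dropped listwise within each requested analysis, not
globally. Group 1 of a two-group test is the level seen first in the file,
and δ > 0 means group 1's mean is larger; "group one greater" maps to the
positive folded Cauchy. Repeated-measures input arrives wide (one column per
cell) and is reshaped to long with a synthetic subject column; every
factorial cell must be mapped to exactly one column.

## Monitoring

Sequential analyses recompute the Bayes factor on every data prefix (rows
in collection order), one trace per prior scale, starting at the first
prefix where the statistic exists; each point equals a from-scratch batch
analysis of that prefix, so there is no state between prefixes. Robustness
curves sweep the prior scale on the full data; scale 0 returns BF = 1
analytically. The stopping-rule evaluator replays a preregistered plan
(minimum per group, maximum per group, threshold on BF or its reciprocal)
against a trace. On simulated null streams with optional stopping from 20
to 100 per group at threshold 10, misleading stops for the alternative occur
in fewer than 10% of replicates, and the log-BF gap between two prior scales
stabilizes once the posteriors have converged (both asserted in the suite).

## Synthetic data

Generators draw from `numpy.random.default_rng` (PCG64); a (spec, seed) pair
fully determines the table. Outcomes are Gaussian with the requested mean
structure — grand mean, sum-to-zero factor effects, correlation ρ for
bivariate pairs, subject random intercepts for within designs — and unit
residual sd. This emulates the model the analyses assume, deliberately not
the quirks of real data (skewed ratings, heteroscedasticity, item effects),
so passing recovery tests demonstrates correctness of the machinery, not
robustness to misspecification. Parameter recovery is asserted for δ ∈
{0, 0.5, 1} (n = 100 per group) and ρ = 0.5 (n = 500) across seeded
replicates.

Two published examples are carried as sufficient-statistics fixtures rather
than raw data. The presidents correlation: the printed 95% CI [.116, .613]
pins down both n (46, from the Fisher-z half-width) and the unrounded
sample correlation (0.3928, from the Fisher-z midpoint); the printed
r = .39 is a 2-decimal display, and using it verbatim shifts the Bayes
factor by ~6%, far more than the reproduction tolerance. The kitchen-roll
replication: group sizes and means are printed, but not the t statistic or
sds; t = −0.754 is recovered once by matching the published two-sided
BF₀₁ = 3.71 at the default scale, after which the one-sided Bayes factor,
its robustness values at r = 1 and r = √2, and the posterior median and
interval are independent predictions (all reproduce within 0.2%). The
sequential-analysis crossing near 55 participants depends on the raw
per-participant collection order, which summaries cannot supply; that check
runs only when the raw CSV is placed at `data/kitchen_rolls.csv`.

The two classic teaching datasets (pain threshold by hair colour, n = 19;
choral-society singer heights, n = 235 with voice part recoded within
gender to a four-level pitch factor) are bundled as plain text.

## Known limitations

* Equal-variance (pooled) t-test only; no paired/Wilcoxon variants and no
  location-shifted ("informed") priors.
* No Kendall's tau, partial correlations, or correlation matrices.
* ANOVA covers fixed and random factorial effects; no covariates (ANCOVA),
  heteroscedastic errors, sphericity diagnostics, post-hoc pairwise tests,
  or multiplicity-adjusted model priors. Repeated-measures designs model
  subject effects only, not crossed item effects.
* Model enumeration is exhaustive and intended for a handful of factors
  (167 models at four factors; the count grows super-exponentially).
* Evidence categories are verbal conventions over a continuous quantity;
  boundary values are assigned to the stronger band by convention.
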