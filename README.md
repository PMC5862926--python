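# defaultbf

Default Bayes-factor hypothesis tests for the analyses behind almost every
experiment in psychology and the life sciences: the Pearson correlation, the
independent-samples *t*-test, one-way and factorial ANOVA, and repeated
measures ANOVA with a random participant factor. The package computes the
Bayes factor BF₁₀ = p(data | H₁) / p(data | H₀) under objective default
priors, together with the surrounding machinery researchers actually use:
posterior summaries and Savage–Dickey checks, model enumeration under the
principle of marginality, Bayesian model averaging with inclusion Bayes
factors, sequential evidence monitoring, prior-robustness curves, verbal
evidence categories, and proportion-wheel values.

It is aimed at researchers who want the numbers these analyses produce —
reproducibly, from a script or shell, with machine-readable output — and at
methodologists who want a tested, readable reference implementation.

## The models

**t-test (JZS).** H₀: δ = 0 versus H₁: δ ~ Cauchy(0, r) on the
standardized effect size δ = (μ₁ − μ₂)/σ, default r = √2/2 ≈ 0.707. The
Bayes factor needs only the t statistic and the group sizes:

    BF₁₀ = ∫ p(t | ν, δ√N_eff) dCauchy(δ; 0, r) / p(t | ν, 0),

with p the noncentral-t density, ν the degrees of freedom and
N_eff = n₁n₂/(n₁+n₂). One-sided tests fold the Cauchy onto a half-line.

**Correlation.** H₀: ρ = 0 versus H₁: ρ ~ stretched-beta(κ) on (−1, 1);
κ = 1 is the uniform prior. The likelihood of the sample correlation r given
ρ is the exact small-sample density of a bivariate-normal sample correlation
(a Gaussian-hypergeometric form); the large-n approximation
(1−ρ²)^((n−1)/2) (1−ρr)^(−(n−3/2)) is available as a fallback.

**ANOVA.** y = μ1 + Σ_t X_t β_t + ε with sum-to-zero effect coding, Jeffreys
prior on (μ, σ²), and per-term g-priors β_t | g_t ~ N(0, g_t σ² I) with
g_t ~ inverse-gamma(1/2, r_t²/2), making standardized effects Cauchy(0, r_t).
Fixed factors use r = 0.5, random participant factors a wider r = 1. Model
spaces are enumerated under marginality (no interaction without its main
effects), nuisance terms live in every model, and posterior model
probabilities / inclusion Bayes factors are computed in log space so tables
survive Bayes factors of order 10³⁹.

## Worked example

The classic question whether taller US presidential candidates attract a
larger share of the popular vote: n = 46 elections, sample correlation
r = .39 (95% CI [.116, .613]).

```python
import defaultbf as d

pres = d.fixture("presidents_stats")   # n and r recovered from the CI
print(pres.n, round(pres.r, 4))        # 46 0.3928

bf2 = d.correlation_bf(pres.stats, d.CorrelationPrior(1.0))
bf1 = d.correlation_bf(pres.stats, d.CorrelationPrior(1.0, "positive"))
print(round(bf2.bf10, 2), round(bf1.bf10, 2))   # 6.3 12.54
print(d.classify(bf2.bf10).text)                # Moderate evidence for H1
print(round(d.wheel_proportion(bf2.bf10), 2))   # 0.86
```

The data are 6.3 times more likely under a correlation than under its
absence (12.5 times if the test is one-sided in the positive direction) —
moderate evidence; on a proportion wheel H₁ claims 86% of the area. The same
result from the shell:

```
$ defaultbf corr --n 46 --r 0.3928 --kappa 1
n = 46, r = 0.3928
BF[H1 vs H0] = 6.3
evidence: Moderate evidence for H1
proportion wheel: 0.863
```

An ANOVA example with the classic pain-threshold data (19 participants in
four hair-colour groups):

```python
from defaultbf.datasets import load_hair_color
res = d.run_anova(load_hair_color(), "Pain Tolerance", fixed=["Hair Color"])
for row in res.comparison:
    print(row.model.name(), round(row.posterior_prob, 3), round(row.bf10, 2))
# Null model 0.077 1.0
# Hair Color 0.923 11.97
```

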