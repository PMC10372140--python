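# kumacens

Inference for the **Kumaraswamy lifetime distribution under progressive
Type-II censoring**: a library plus a `kumacens` command-line tool for
reliability and survival studies whose responses live on the unit interval
(proportions of capacity, normalized lifetimes, test scores).

The Kumaraswamy distribution has density and distribution function

    f(x) = α β x^{α−1} (1 − x^α)^{β−1},      F(x) = 1 − (1 − x^α)^β,   0 < x < 1,

with two positive shape parameters.  Its closed-form, invertible cdf makes
censored-data likelihoods and quantiles cheap, which is why it is popular
for bounded hydrological and reliability data where the Beta distribution
is awkward.

A progressive Type-II censoring plan (n, m, R₁…Rₘ) puts n units on test,
observes m failures, and withdraws Rᵢ surviving units at the i-th failure
(Σ Rᵢ = n − m).  Given the ordered failures x₍₁₎ < … < x₍ₘ₎ the package
provides:

- **Frequentist estimation** — maximum likelihood via a 1-D profile solve
  (β̂(α) = −m / Σ (Rᵢ+1) log(1 − x₍ᵢ₎^α) is closed-form), maximum product
  spacings, observed Fisher information, and Wald confidence intervals.
- **Bayesian estimation** with independent Gamma(a₁,b₁), Gamma(a₂,b₂)
  priors — closed-form Lindley-approximation estimates and an
  MH-within-Gibbs sampler (exact gamma update for β, random-walk
  Metropolis for α), under squared-error, LINEX and general-entropy
  losses, with Chen–Shao highest-posterior-density intervals and
  moment-matching prior elicitation from past samples.
- **Optimal censoring design** — rank candidate removal plans by the
  determinant or trace of the asymptotic variance–covariance matrix, or by
  the delta-method variance of a log-quantile.
- **Goodness of fit** — complete-sample model comparison of Kumaraswamy,
  generalized exponential, Burr XII and Beta fits by NLC/AIC/AICc/BIC and
  the exact Kolmogorov–Smirnov statistic.
- **Simulation harness** — seeded Monte-Carlo tables of average, MSE,
  interval length and coverage for any estimator × scheme × truth grid.

## Worked example

The packaged dataset is the February water capacity of the Shasta
reservoir (California) for 1991–2010, twenty proportions in (0, 1):

```python
>>> import kumacens as kc
>>> x = kc.load_shasta()
>>> kc.compare_models(x)[["family", "nlc", "aic", "ks_stat"]]
   family        nlc        aic   ks_stat
0     Kum -13.474713 -22.949427  0.220880
1    Beta -12.561924 -21.123848  0.235939
2    Burr -11.505934 -19.011868  0.224745
3  GenExp  -4.792534  -5.585069  0.294882
```

The Kumaraswamy fit attains the smallest negative log-likelihood criterion
(−13.47) and the smallest AIC, so it is the preferred model for these
data.  Fitting it directly:

```python
>>> from kumacens import PCS2Sample, complete_scheme, mle_fit, asymptotic_ci
>>> import numpy as np
>>> sample = PCS2Sample(np.sort(x), complete_scheme(len(x)))
>>> fit = mle_fit(sample)
>>> fit.estimates
KumParams(alpha=6.347576581272414, beta=4.489396616204309)
>>> [round(float(v), 4) for ci in asymptotic_ci(fit, 0.95) for v in (ci.lower, ci.upper)]
[3.2949, 9.4002, 0.4891, 8.4897]
```

α̂ ≈ 6.35 and β̂ ≈ 4.49 describe a left-skewed capacity distribution
concentrated near 0.8; the brackets are 95% Wald intervals for α and β.
A censored variant of the same analysis needs only a removal plan:

```python
>>> scheme = kc.validate_scheme(20, 10, (0,)*9 + (10,))   # Type-II: stop at 10th failure
>>> censored = kc.censor_complete_sample(x, scheme, seed=1)
>>> mle_fit(censored).estimates
KumParams(alpha=3.934210558243473, beta=1.4661722199083287)
```

From the shell the same steps are `kumacens gof`, `kumacens generate`,
`kumacens fit`, `kumacens bayes`, `kumacens design` and
`kumacens simulate` (see `kumacens --help`).

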