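# Methods

## Model and sampling design

The Kumaraswamy distribution on (0, 1) has cdf F(x) = 1 − (1 − x^α)^β with
positive shapes α, β; α = β = 1 is Uniform(0, 1).  Under a progressive
Type-II censoring plan (n, m, R₁…Rₘ) — n units on test, Rᵢ surviving
units withdrawn at the i-th of m observed failures, Σ Rᵢ = n − m — the
joint density of the ordered failures is

    L(α, β) = C ∏ᵢ f(x₍ᵢ₎) (1 − F(x₍ᵢ₎))^{Rᵢ},

with an ordering constant C = n(n − R₁ − 1)… that does not involve the
parameters.  **C is excluded from every reported log-likelihood** (an
explicit `include_constant` switch restores it): information criteria,
likelihood comparisons and all derivative-based machinery use the
parameter-dependent part only, so complete-sample results agree with the
ordinary i.i.d. likelihood.

Samples are generated by the Balakrishnan–Sandhu uniform transformation
(cumulative removal counts taken from the tail of the plan), which yields
exact-distribution progressively censored order statistics, followed by
the closed-form Kumaraswamy quantile.  This is validated in the test
suite against the closed-form law of the sample minimum,
F₍₁₎ = 1 − (1 − F)ⁿ, and against a brute-force order-statistic oracle for
conventional Type-II plans.

## Frequentist estimation

The score equation in β has the closed-form solution
β̂(α) = −m / Σ (Rᵢ+1) log(1 − x₍ᵢ₎^α).  Substituting it reduces the MLE to
a one-dimensional root-find on the profile score in α, solved by a
geometrically grown sign-change bracket from the default start α = 1 (the
scale-free uniform case) and Brent's method (xtol 1e−12, 200-iteration
cap, non-convergence flagged).  Profiling makes existence and uniqueness
easy to inspect and is far more robust than a joint 2-D Newton iteration.

The maximum-product-spacings (MPS) criterion maximizes

    S(α, β) = Σᵢ₌₁^{m+1} log[(1 − x₍ᵢ₋₁₎^α)^β − (1 − x₍ᵢ₎^α)^β]
              + Σᵢ β Rᵢ log(1 − x₍ᵢ₎^α),

with boundary conventions x₍₀₎ = 0, x₍ₘ₊₁₎ = 1.  Spacings are evaluated
in log space (log D = A₍ᵢ₋₁₎ + log(−expm1(Aᵢ − A₍ᵢ₋₁₎)) with
A = β log1p(−x^α)) to avoid the catastrophic cancellation the plain form
suffers for close order statistics or extreme shapes.  Optimization is
L-BFGS-B with the analytic gradient, then a root polish of the two score
equations; tied adjacent observations make the criterion −∞ and are
rejected.  The MPS point estimate carries the inverse observed
*likelihood* information as its reported dispersion, documented as an
approximation — the spacings criterion has no information identity, and
Monte-Carlo MSE is the dispersion summary used in simulation tables.

Both optimizers are checked on dozens of random instances against an
independent two-stage log-spaced grid-search oracle.

The observed information uses the closed-form second derivatives
(l_ββ = −m/β² exactly); the 2×2 inverse is analytic, and Wald intervals
truncate negative lower endpoints to 0 (flagged) since the parameters are
positive.

## Bayesian estimation

Independent Gamma(a₁, b₁) and Gamma(a₂, b₂) priors on α and β give the
joint posterior (up to a constant that is never evaluated)

    π(α, β | x) ∝ α^{m+a₁−1} β^{m+a₂−1} [∏ x₍ᵢ₎^{α−1}/(1 − x₍ᵢ₎^α)]
                  · exp{ β Σ (Rᵢ+1) log(1 − x₍ᵢ₎^α) − b₁α − b₂β }.

**Lindley approximation.**  Every SE/LINEX/GE Bayes estimate is a ratio
of posterior integrals, expanded to second order around the MLE using
log-likelihood derivatives up to third order (l_αββ = 0 and
l_βββ = 2m/β³ hold exactly for this model and are asserted in tests;
l_ααα and l_ααβ are cross-checked against finite differences) and
log-prior gradients ρ_α = (a₁−1)/α̂ − b₁, ρ_β = (a₂−1)/β̂ − b₂.  The σ
matrix is taken as the inverse of the full negative Hessian — consistent
with the asymptotic variance–covariance matrix, and making the ρ = 0,
third-derivative-free reduction collapse exactly to the MLE — rather than
elementwise −1/l_ij, which is the other convention sometimes seen; the
choice matters only at third-order accuracy.  The LINEX and GE outer
transforms require a positive inner expression; at small m the expansion
can overshoot, and this raises an explicit error (never a silent clamp)
so callers can fall back to MCMC.  A 400×400 2-D quadrature of the joint
posterior serves as the oracle for the diffuse-prior SE estimates.

**MH-within-Gibbs.**  The full conditional of β given α is exactly
Gamma(m + a₂, rate b₂ − Σ (Rᵢ+1) log(1 − x₍ᵢ₎^α)) (the rate is positive
because every log term is negative) and is Gibbs-updated.  The full
conditional of α — which carries the factor β on the censoring log-terms;
the single-parameter form without it is exposed at `beta=1` — has no
standard form and is updated by random-walk Metropolis with a normal
proposal.  The proposal scale defaults to the asymptotic standard error
of α̂ ("auto"); chains start at the MLE.  Proposals ≤ 0 are rejected
outright, which is the correct zero-density rejection and preserves
detailed balance.  Defaults: 10,000 draws, 2,000 burn-in, no thinning.
Correctness is tested by a two-sample Kolmogorov–Smirnov comparison
against fine-grid draws from the joint posterior on a small instance and
by the analytic gamma-conditional moments with the α-chain frozen.

Loss-based point estimates from the retained chain: posterior mean (SE),
−(1/c) log mean e^{−cθ} (LINEX), (mean θ^{−q})^{−1/q} (GE), the latter
two computed by log-sum-exp so extreme asymmetry parameters cannot
overflow.  HPD intervals are Chen–Shao shortest windows over the sorted
draws, with ties broken toward the smallest left index under a relative
tolerance of 1e−12 (exact floating-point ties are not reproducible).

**Elicitation.**  Given MLEs from k past samples, the gamma
hyperparameters are moment-matched: b = mean/variance, a = mean²/variance
per parameter, with the (k−1)-denominator variance.  The simulation
harness's "elicit" mode reproduces the historical-data protocol — 500
complete samples of size 60 drawn at the cell's true parameters — because
the generating parameters of the original "historical data" are not
recoverable; note the elicited prior mean then inherits the finite-sample
(≈5% upward at n=60) bias of the MLE, which propagates into Bayes-cell
averages at about the same order.

## Optimal censoring design

Candidate plans sharing (n, m) are ranked by three criteria, each
minimized: det and trace of the asymptotic variance–covariance matrix,
and the delta-method variance of log T_u for the quantile
T_u = (1 − (1−u)^{1/β})^{1/α} on the default grid u ∈ {0.25, 0.5, 0.75}.
When evaluated by simulation, each criterion is the Monte-Carlo average
of its per-replicate observed-information value; the per-scheme RNG
stream is keyed by the scheme content (not its list position), so
criterion values are invariant to the order schemes are supplied.
Exhaustive enumeration of all admissible removal vectors is out of scope;
the user supplies the candidate list.

## Goodness of fit

Complete-sample comparison of four two-parameter families: Kumaraswamy,
generalized exponential F = (1 − e^{−λx})^θ, Burr XII F = 1 − (1+x^c)^{−k}
and Beta(a, b) — the canonical parameterizations.  Kumaraswamy uses the
profile MLE, Beta the scipy beta MLE with fixed support, and the other two
a 3-start Nelder–Mead in log-parameter space.  With k = 2 parameters:
AIC = 4 − 2ℓ, AICc = AIC + 12/(n−3), BIC = 2 log n − 2ℓ, NLC = −ℓ.  The
K-S statistic is the exact supremum over the n empirical jump points and
its p-value uses the exact finite-n Kolmogorov distribution, which is the
appropriate reference at n = 20 (the asymptotic series is visibly off
there).  Model-comparison power is limited: Beta (and Burr XII near the
origin) can approximate many Kumaraswamy shapes so closely that at
n = 200 the true family wins AIC only by a plurality except at strongly
separating shapes — the test suite quantifies this rather than assuming
perfect selection.

## Simulation harness

Per replicate: generate a censored sample, run the requested estimators,
record points and intervals; aggregate average, MSE against the truth,
average interval length, and coverage percentage.  Replicate r uses an
RNG stream derived from (master seed, r), so tables are bit-reproducible
and order-independent; non-convergent replicates are dropped and counted.
Problem sizes used by the reproduction script — 1000 replicates for the
MLE cells, 200 replicates of 10,000-draw chains for the Bayes cell —
were chosen to put Monte-Carlo standard errors well below the effects of
interest while keeping a single-core run to a few minutes.

## What the synthetic generator does and does not emulate

The generator draws i.i.d. Kumaraswamy lifetimes censored exactly
according to the stated plan: the idealized design.  Real reliability
data bring tied recorded values (ties are kept in stable order here, and
tied observations break the MPS criterion), rounding, unit heterogeneity
and informative withdrawal, none of which are modeled.  Passing tests
therefore certify the estimators under the model's own assumptions, not
robustness to their violation.

## Known limitations

- The Lindley expansion degrades at small m (overshoot raised as an
  error by design); its tabulated behaviour depends on the σ convention,
  so only its structural identities are asserted, not published tables.
- MPS dispersion is Monte-Carlo only; the reported information-based
  vcov at the MPS point is a convenience approximation.
- Applying a removal plan to an observed complete dataset randomizes
  which units are withdrawn; published point estimates from such
  censored real-data exercises are not reproducible without the original
  removal realization, so only the procedure (not those numbers) is
  covered.
- Single-chain sampler; no Gelman–Rubin machinery or adaptive proposals.
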