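"""Lindley-approximation Bayes estimates under SE, LINEX and GE losses.

With independent Gamma(a1, b1) and Gamma(a2, b2) priors on the two shape
parameters, every Bayes point estimate is a ratio of two double integrals
over the posterior.  Lindley's expansion approximates such ratios around
the MLE using log-likelihood derivatives up to third order and log-prior
first derivatives:

    E[g | x] ~ g(th) + (corrections built from g_i, g_ij, rho_i,
                        sigma_ij and l_ijk, all evaluated at the MLE)

where sigma is the inverse of the negative Hessian of the log-likelihood
(identical to the asymptotic variance-covariance matrix) and
rho_a = (a1-1)/a - b1, rho_b = (a2-1)/b - b2.

For the Kumaraswamy PCS-II likelihood several derivatives vanish or
close-form: l_bb = -m/b^2, l_bbb = 2m/b^3, l_abb = 0, which collapses the
general expansion to the compact forms implemented here.

Loss functions and their Bayes rules:

    SE     g = theta          estimate = posterior mean
    LINEX  g = exp(-c*theta)  estimate = -(1/c) log E[exp(-c*theta)]
    GE     g = theta**(-q)    estimate = (E[theta**(-q)])**(-1/q)

The LINEX/GE outer transforms can overshoot into a non-positive inner
expression at small m; that condition raises ``LindleyOvershootError``
(never silently clamped) so callers can fall back to MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import PCS2Sample
from .core import KumParams
from .frequentist import FitResult

__all__ = [
    "GammaPriors",
    "LossSpec",
    "LindleyWorkspace",
    "LindleyOvershootError",
    "lindley_workspace",
    "lindley_estimate",
]


@dataclass(frozen=True)
class GammaPriors:
    """Gamma shape/rate hyperparameters: alpha ~ G(a1, b1), beta ~ G(a2, b2)."""

    a1: float
    b1: float
    a2: float
    b2: float

    def __post_init__(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) <= 0:
            raise ValueError("all gamma hyperparameters must be positive")


@dataclass(frozen=True)
class LossSpec:
    """Loss function tag with its asymmetry parameter (c for LINEX, q for GE)."""

    kind: str  # "SE", "LINEX" or "GE"
    c: float = 0.0
    q: float = 0.0

    def __post_init__(self) -> None:
        kind = self.kind.upper()
        object.__setattr__(self, "kind", kind)
        if kind not in {"SE", "LINEX", "GE"}:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if kind == "LINEX" and self.c == 0:
            raise ValueError("LINEX requires a nonzero c")
        if kind == "GE" and self.q == 0:
            raise ValueError("GE requires a nonzero q")


class LindleyOvershootError(ArithmeticError):
    """The LINEX/GE inner expression went non-positive (expansion overshoot)."""


@dataclass
class LindleyWorkspace:
    sigma: np.ndarray  # inverse negative Hessian at the MLE
    l_aaa: float
    l_aab: float  # = l_aba = l_baa
    l_abb: float  # identically 0 for this likelihood
    l_bbb: float  # = 2m / beta_hat^3
    rho_alpha: float
    rho_beta: float
    mle: KumParams


def lindley_workspace(
    sample: PCS2Sample, mle: FitResult, priors: GammaPriors
) -> LindleyWorkspace:
    """Evaluate every derivative the expansion needs, at the MLE."""
    a, b = mle.estimates.alpha, mle.estimates.beta
    x = sample.observations
    m = sample.m
    R = sample.scheme.removals_array()
    xa = np.power(x, a)
    lx = np.log(x)
    omx = 1.0 - xa

    # third derivative of the log-likelihood in alpha; the bracketed factor
    # x^a(1-x^a)^2 + 2x^{2a}(1-x^a) over (1-x^a)^4 simplifies to
    # x^a (1+x^a) / (1-x^a)^3
    l_aaa = 2.0 * m / a**3 - np.sum(
        (b * (R + 1.0) - 1.0) * lx**3 * xa * (1.0 + xa) / omx**3
    )
    l_aab = -np.sum((R + 1.0) * xa * lx**2 / omx**2)
    l_bbb = 2.0 * m / b**3

    sigma = np.asarray(mle.vcov, dtype=float)
    return LindleyWorkspace(
        sigma=sigma,
        l_aaa=float(l_aaa),
        l_aab=float(l_aab),
        l_abb=0.0,
        l_bbb=float(l_bbb),
        rho_alpha=(priors.a1 - 1.0) / a - priors.b1,
        rho_beta=(priors.a2 - 1.0) / b - priors.b2,
        mle=mle.estimates,
    )


def _correction_terms(ws: LindleyWorkspace):
    """(Q_a + P_a/2, Q_b + P_b/2): the additive expansion corrections for
    g = alpha and g = beta respectively."""
    s = ws.sigma
    s_aa, s_ab, s_bb = s[0, 0], s[0, 1], s[1, 1]
    q_a = ws.rho_alpha * s_aa + ws.rho_beta * s_ab
    q_b = ws.rho_alpha * s_ab + ws.rho_beta * s_bb
    p_a = s_aa * (ws.l_aaa * s_aa + 2.0 * ws.l_aab * s_ab) + s_ab * (
        ws.l_aab * s_aa + ws.l_bbb * s_bb
    )
    p_b = s_ab * (ws.l_aaa * s_aa + 2.0 * ws.l_aab * s_ab) + s_bb * (
        ws.l_aab * s_aa + ws.l_bbb * s_bb
    )
    return q_a + 0.5 * p_a, q_b + 0.5 * p_b


def lindley_estimate(
    sample: PCS2Sample,
    mle: FitResult,
    priors: GammaPriors,
    loss: LossSpec = LossSpec("SE"),
) -> KumParams:
    """Approximate posterior point estimates of (alpha, beta) under ``loss``."""
    ws = lindley_workspace(sample, mle, priors)
    a_hat, b_hat = ws.mle.alpha, ws.mle.beta
    s_aa, s_bb = ws.sigma[0, 0], ws.sigma[1, 1]
    corr_a, corr_b = _correction_terms(ws)

    if loss.kind == "SE":
        return KumParams(a_hat + corr_a, b_hat + corr_b)

    if loss.kind == "LINEX":
        c = loss.c
        out = []
        for theta, corr, s_ii in ((a_hat, corr_a, s_aa), (b_hat, corr_b, s_bb)):
            g = np.exp(-c * theta)
            g1 = -c * g
            g2 = c**2 * g
            inner = g + 0.5 * g2 * s_ii + g1 * corr
            if inner <= 0:
                raise LindleyOvershootError(
                    f"LINEX(c={c}) inner expression non-positive ({inner:.3e}); "
                    "Lindley expansion overshoot - consider MCMC"
                )
            out.append(-np.log(inner) / c)
        return KumParams(*out)

    # GE
    q = loss.q
    out = []
    for theta, corr, s_ii in ((a_hat, corr_a, s_aa), (b_hat, corr_b, s_bb)):
        g = theta ** (-q)
        g1 = -q * theta ** (-q - 1.0)
        g2 = q * (q + 1.0) * theta ** (-q - 2.0)
        inner = g + 0.5 * g2 * s_ii + g1 * corr
        if inner <= 0:
            raise LindleyOvershootError(
                f"GE(q={q}) inner expression non-positive ({inner:.3e}); "
                "Lindley expansion overshoot - consider MCMC"
            )
        out.append(inner ** (-1.0 / q))
    return KumParams(*out)
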