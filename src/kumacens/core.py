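"""Kumaraswamy distribution primitives.

The Kumaraswamy distribution is a two-shape-parameter family on the unit
interval, similar in flexibility to the Beta distribution but with a
closed-form, analytically invertible cdf

    F(x) = 1 - (1 - x**alpha)**beta,        0 < x < 1,

which makes quantiles, random variate generation and censored-sample
likelihoods cheap.  With alpha = beta = 1 it reduces to Uniform(0, 1).

All heavy-lifting modules (estimation, censoring, Bayes) build on the four
primitives here.  Log-forms use ``log1p``/``expm1`` so that densities and
spacings remain accurate for x near 0 or 1 and for extreme shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KumParams",
    "kum_pdf",
    "kum_logpdf",
    "kum_cdf",
    "kum_logsf",
    "kum_quantile",
    "kum_rvs",
]


@dataclass(frozen=True)
class KumParams:
    """The two positive shape parameters (alpha, beta)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha}")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError(f"beta must be a positive finite real, got {self.beta}")


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def kum_logpdf(x, params: KumParams):
    """Log-density log(alpha*beta) + (alpha-1)log x + (beta-1)log(1-x^alpha).

    At the boundary points 0 and 1 the continuous limit is returned
    (``-inf`` where the density limit is 0, ``+inf`` where it diverges),
    matching the convention used for the pdf itself.
    """
    a, b = params.alpha, params.beta
    x = _as_array(x)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        xa = np.power(x, a)
        out = (
            np.log(a)
            + np.log(b)
            + (a - 1.0) * np.log(x)
            + (b - 1.0) * np.log1p(-xa)
        )
    # continuous limits at the boundary
    out = np.where(x == 0.0, _boundary_logpdf_at_zero(a, b), out)
    out = np.where(x == 1.0, _boundary_logpdf_at_one(a, b), out)
    return out if out.ndim else float(out)


def _boundary_logpdf_at_zero(a: float, b: float) -> float:
    if a < 1:
        return np.inf
    if a == 1:
        return float(np.log(a) + np.log(b))
    return -np.inf


def _boundary_logpdf_at_one(a: float, b: float) -> float:
    if b < 1:
        return np.inf
    if b == 1:
        return float(np.log(a) + np.log(b))
    return -np.inf


def kum_pdf(x, params: KumParams):
    """Density alpha*beta*x^(alpha-1)*(1-x^alpha)^(beta-1) on (0, 1).

    Values at x in {0, 1} are the continuous limits (0, finite, or +inf
    depending on the shapes) rather than an error, so plots and spacing
    boundary terms evaluate cleanly.
    """
    with np.errstate(over="ignore"):
        return np.exp(kum_logpdf(x, params))


def kum_cdf(x, params: KumParams):
    """Distribution function 1 - (1 - x^alpha)^beta for x in [0, 1]."""
    a, b = params.alpha, params.beta
    x = _as_array(x)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    # -expm1(beta*log1p(-x^a)) is exact at both endpoints (x=1 -> log 0)
    with np.errstate(divide="ignore"):
        out = -np.expm1(b * np.log1p(-np.power(x, a)))
    return out if out.ndim else float(out)


def kum_logsf(x, params: KumParams):
    """Log survival function beta*log(1 - x^alpha); stable for x near 1."""
    a, b = params.alpha, params.beta
    x = _as_array(x)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = b * np.log1p(-np.power(x, a))
    return out if out.ndim else float(out)


def kum_quantile(u, params: KumParams):
    """Quantile T_u = (1 - (1-u)^(1/beta))^(1/alpha) for u in (0, 1).

    Exact functional inverse of :func:`kum_cdf` on the open interval.
    """
    a, b = params.alpha, params.beta
    u = _as_array(u)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie in the open interval (0, 1)")
    # 1-(1-u)^(1/b) = -expm1(log1p(-u)/b)
    inner = -np.expm1(np.log1p(-u) / b)
    out = np.power(inner, 1.0 / a)
    return out if out.ndim else float(out)


def kum_rvs(count: int, params: KumParams, seed=None) -> np.ndarray:
    """i.i.d. draws by inverse-transform sampling; bit-reproducible per seed.

    ``seed`` may be an int or an existing :class:`numpy.random.Generator`.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=count)
    # keep u strictly inside (0,1); P(u==0) is negligible but not zero
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return kum_quantile(u, params)
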