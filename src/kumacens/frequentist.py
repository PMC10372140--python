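"""Likelihood and product-spacings estimation for PCS-II Kumaraswamy data.

The progressively censored log-likelihood is

    l(a, b) = m log a + m log b + (a-1) sum log x_(i)
              + sum (b(R_i + 1) - 1) log(1 - x_(i)^a)        (+ log C),

where C is the ordering constant of the censored-sample density.  C does
not involve the parameters, so it is excluded by default everywhere; all
information criteria are computed on the parameter-dependent part.

The MLE exploits the closed form b_hat(a) = -m / sum (R_i+1) log(1-x^a):
substituting it reduces the problem to a one-dimensional root-find on the
profile score in alpha, which also makes existence/uniqueness checks cheap.

The maximum-product-spacings (MPS) estimator maximizes the log-product of
cdf spacings between consecutive order statistics (with censoring weights)

    S(a, b) = sum_{i=1}^{m+1} log[(1-x_(i-1)^a)^b - (1-x_(i)^a)^b]
              + sum_i b R_i log(1 - x_(i)^a),

with boundary conventions x_(0) = 0 and x_(m+1) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .censoring import PCS2Sample
from .core import KumParams

__all__ = [
    "FitResult",
    "ConfidenceInterval",
    "loglik_pcs2",
    "beta_hat_given_alpha",
    "mle_fit",
    "mps_objective",
    "mps_gradient",
    "mps_fit",
    "observed_information",
    "asymptotic_ci",
]


@dataclass
class FitResult:
    estimates: KumParams
    vcov: np.ndarray
    loglik_at_mle: float
    method: str  # "MLE" or "MPS"
    converged: bool
    n_iterations: int

    def __post_init__(self) -> None:
        self.vcov = np.asarray(self.vcov, dtype=float)


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _log_ordering_constant(sample: PCS2Sample) -> float:
    n, R = sample.n, sample.scheme.removals
    terms = []
    removed = 0
    for i, _ in enumerate(R):
        terms.append(n - removed - i)
        removed += R[i]
    return float(np.sum(np.log(terms)))


def loglik_pcs2(
    params: KumParams, sample: PCS2Sample, include_constant: bool = False
) -> float:
    """PCS-II log-likelihood; the ordering constant only if requested."""
    a, b = params.alpha, params.beta
    x = sample.observations
    m = sample.m
    R = sample.scheme.removals_array()
    log1mxa = np.log1p(-np.power(x, a))
    ll = (
        m * np.log(a)
        + m * np.log(b)
        + (a - 1.0) * np.sum(np.log(x))
        + np.sum((b * (R + 1.0) - 1.0) * log1mxa)
    )
    if include_constant:
        ll += _log_ordering_constant(sample)
    return float(ll)


def beta_hat_given_alpha(sample: PCS2Sample, alpha: float) -> float:
    """Closed-form conditional MLE b_hat(a) = -m / sum (R_i+1) log(1-x^a)."""
    x = sample.observations
    R = sample.scheme.removals_array()
    denom = np.sum((R + 1.0) * np.log1p(-np.power(x, alpha)))
    return float(-sample.m / denom)


def _profile_score(alpha: float, sample: PCS2Sample) -> float:
    # envelope theorem: d/da of the profile log-likelihood equals the
    # partial score in alpha evaluated at (a, b_hat(a))
    x = sample.observations
    m = sample.m
    R = sample.scheme.removals_array()
    b = beta_hat_given_alpha(sample, alpha)
    xa = np.power(x, alpha)
    lx = np.log(x)
    return float(
        m / alpha
        + np.sum(lx)
        - np.sum((b * (R + 1.0) - 1.0) * xa * lx / (1.0 - xa))
    )


def mle_fit(sample: PCS2Sample, init_alpha: float = 1.0) -> FitResult:
    """Maximum-likelihood fit by a bracketed 1-D solve of the profile score.

    The bracket is grown geometrically from ``init_alpha`` until the score
    changes sign, then Brent's method finds the root; ``b_hat(alpha)`` is
    exact by construction.  The variance-covariance matrix is the inverse
    observed information at the optimum.
    """
    if sample.m < 2:
        raise ValueError("need at least two observed failures")
    if np.allclose(sample.observations, sample.observations[0]):
        raise ValueError("degenerate sample: all observations equal")

    f = lambda a: _profile_score(a, sample)
    lo = hi = float(init_alpha)
    f0 = f(lo)
    n_iter = 0
    converged = True
    if f0 > 0:  # score positive: optimum lies to the right
        hi = lo * 2.0
        while f(hi) > 0 and n_iter < 200:
            lo, hi = hi, hi * 2.0
            n_iter += 1
    else:
        lo = hi / 2.0
        while f(lo) < 0 and n_iter < 200:
            hi, lo = lo, lo / 2.0
            n_iter += 1
    if n_iter >= 200:
        converged = False
        alpha_hat = hi
    else:
        alpha_hat, res = optimize.brentq(
            f, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=200, full_output=True
        )
        converged = res.converged
        n_iter += res.iterations
    beta_hat = beta_hat_given_alpha(sample, alpha_hat)
    params = KumParams(alpha_hat, beta_hat)
    _, vcov = observed_information(params, sample)
    return FitResult(
        estimates=params,
        vcov=vcov,
        loglik_at_mle=loglik_pcs2(params, sample),
        method="MLE",
        converged=converged,
        n_iterations=n_iter,
    )


def _spacing_logs(params: KumParams, sample: PCS2Sample):
    """log survivor values A_i = b*log(1-x_i^a) at 0, x_(1..m), 1."""
    a, b = params.alpha, params.beta
    x = sample.observations
    A = np.empty(sample.m + 2)
    A[0] = 0.0
    with np.errstate(divide="ignore"):  # x^a can round to 1 for extreme a
        A[1:-1] = b * np.log1p(-np.power(x, a))
    A[-1] = -np.inf
    return A


def mps_objective(params: KumParams, sample: PCS2Sample) -> float:
    """Log product-spacings criterion S(alpha, beta); -inf on tied data."""
    b = params.beta
    x = sample.observations
    R = sample.scheme.removals_array()
    A = _spacing_logs(params, sample)
    with np.errstate(invalid="ignore"):
        diffs = A[1:] - A[:-1]  # = A_i - A_{i-1} <= 0
    if np.any(diffs == 0.0) or np.any(np.isnan(diffs)):
        if np.any(np.diff(sample.observations) == 0.0):
            warnings.warn("zero spacing (tied adjacent observations); S = -inf")
        return -np.inf
    # log D_i = A_{i-1} + log(1 - exp(A_i - A_{i-1}))
    with np.errstate(divide="ignore"):
        log_spacings = A[:-1] + np.log(-np.expm1(diffs))
        log1mxa = np.log1p(-np.power(x, params.alpha))
    mask = R > 0
    tail = np.sum(b * R[mask] * log1mxa[mask])
    return float(np.sum(log_spacings) + tail)


def mps_gradient(params: KumParams, sample: PCS2Sample) -> np.ndarray:
    """Analytic gradient (dS/dalpha, dS/dbeta) of the spacings criterion."""
    a, b = params.alpha, params.beta
    x = sample.observations
    R = sample.scheme.removals_array()
    m = sample.m

    # augmented grids with the 0/1 boundary points
    with np.errstate(divide="ignore"):
        L = np.concatenate(([0.0], np.log1p(-np.power(x, a)), [-np.inf]))  # log(1-x^a)
    # d/da of (1-x^a)^b at each grid point: -b (1-x^a)^(b-1) x^a log x
    xalogx = np.concatenate(([0.0], np.power(x, a) * np.log(x), [0.0]))
    with np.errstate(over="ignore", invalid="ignore"):
        dFda = -b * np.exp((b - 1.0) * L) * xalogx
        dFda = np.where(xalogx == 0.0, 0.0, dFda)
        # d/db of (1-x^a)^b = (1-x^a)^b log(1-x^a)
        dFdb = np.exp(b * L) * L
        dFdb = np.where(np.isinf(L), 0.0, dFdb)

    A = b * L
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.exp(A[:-1]) - np.exp(A[1:])  # spacings D_i, i = 1..m+1
        grad_a = np.sum((dFda[:-1] - dFda[1:]) / D)
        grad_b = np.sum((dFdb[:-1] - dFdb[1:]) / D)
        # censoring tail term b*R_i*log(1-x^a)
        lx = np.log(x)
        xam = np.power(x, a)
        mask = R > 0
        grad_a += np.sum(b * R[mask] * (-xam[mask] * lx[mask] / (1.0 - xam[mask])))
        grad_b += np.sum(R[mask] * np.log1p(-xam[mask]))
    return np.array([grad_a, grad_b])


def mps_fit(sample: PCS2Sample, init: KumParams | None = None) -> FitResult:
    """Maximum-product-spacings fit (2-D quasi-Newton, analytic gradient).

    The reported variance-covariance matrix is the inverse observed
    *likelihood* information evaluated at the MPS point; this is an
    approximation for reporting only (the spacings criterion has no
    analogue of the information identity here).
    """
    if sample.m < 2:
        raise ValueError("need at least two observed failures")
    if np.any(np.diff(sample.observations) == 0.0):
        raise ValueError("tied observations: MPS criterion is degenerate")
    if init is None:
        try:
            init = mle_fit(sample).estimates
        except Exception:
            init = KumParams(1.0, 1.0)

    def negS(p):
        val = -mps_objective(KumParams(p[0], p[1]), sample)
        return val if np.isfinite(val) else 1e300

    def negG(p):
        g = -mps_gradient(KumParams(p[0], p[1]), sample)
        return np.where(np.isfinite(g), g, 0.0)

    res = optimize.minimize(
        negS,
        x0=[init.alpha, init.beta],
        jac=negG,
        method="L-BFGS-B",
        bounds=[(1e-8, None), (1e-8, None)],
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
    )
    # polish to drive the score equations to machine zero
    sol = optimize.root(negG, res.x, method="hybr", tol=1e-12)
    xopt = sol.x if (sol.success and np.all(sol.x > 0)) else res.x
    params = KumParams(float(xopt[0]), float(xopt[1]))
    _, vcov = observed_information(params, sample)
    return FitResult(
        estimates=params,
        vcov=vcov,
        loglik_at_mle=loglik_pcs2(params, sample),
        method="MPS",
        converged=bool(res.success or sol.success),
        n_iterations=int(res.nit),
    )


def observed_information(params: KumParams, sample: PCS2Sample):
    """Observed information matrix [-l_aa, -l_ab; -l_ab, -l_bb] and inverse.

    Second derivatives in closed form:

        l_aa = -m/a^2 - sum (b(R_i+1)-1) x^a (log x)^2 / (1-x^a)^2
        l_bb = -m/b^2
        l_ab = -sum (R_i+1) x^a log x / (1-x^a)

    The 2x2 inverse is computed analytically.
    """
    a, b = params.alpha, params.beta
    x = sample.observations
    m = sample.m
    R = sample.scheme.removals_array()
    xa = np.power(x, a)
    lx = np.log(x)
    l_aa = -m / a**2 - np.sum((b * (R + 1.0) - 1.0) * xa * lx**2 / (1.0 - xa) ** 2)
    l_bb = -m / b**2
    l_ab = -np.sum((R + 1.0) * xa * lx / (1.0 - xa))
    info = np.array([[-l_aa, -l_ab], [-l_ab, -l_bb]])
    det = info[0, 0] * info[1, 1] - info[0, 1] ** 2
    if abs(det) < 1e-300 or not np.isfinite(det):
        cond = np.linalg.cond(info)
        raise np.linalg.LinAlgError(
            f"observed information is singular (condition number {cond:.3e})"
        )
    inv = np.array([[info[1, 1], -info[0, 1]], [-info[0, 1], info[0, 0]]]) / det
    return info, inv


def asymptotic_ci(fit: FitResult, level: float = 0.95):
    """Wald intervals theta_hat +/- z_{gamma/2} * se for alpha and beta.

    Negative lower endpoints are truncated to 0 (flagged), since the
    parameters are positive by definition.
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for est, var in zip(
        (fit.estimates.alpha, fit.estimates.beta), np.diag(fit.vcov)
    ):
        se = np.sqrt(max(var, 0.0))
        lo, hi = est - z * se, est + z * se
        truncated = lo < 0
        out.append(ConfidenceInterval(max(lo, 0.0), hi, level, truncated))
    return tuple(out)
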