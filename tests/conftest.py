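import numpy as np
import pytest

from kumacens import (
    CensoringScheme,
    KumParams,
    PCS2Sample,
    generate_pcs2_sample,
    load_shasta,
    validate_scheme,
)


@pytest.fixture(scope="session")
def shasta() -> np.ndarray:
    return load_shasta()


@pytest.fixture(scope="session")
def shasta_complete(shasta) -> PCS2Sample:
    n = len(shasta)
    return PCS2Sample(np.sort(shasta), CensoringScheme(n, n, (0,) * n))


@pytest.fixture
def small_sample() -> PCS2Sample:
    """Deterministic censored sample for closed-form/oracle checks."""
    scheme = validate_scheme(8, 5, (2, 0, 1, 0, 0))
    return PCS2Sample(np.array([0.12, 0.30, 0.41, 0.66, 0.83]), scheme)


def random_pcs2_sample(seed: int, n: int = 30, m: int = 30):
    """A reproducible PCS-II draw at randomized shapes for oracle sweeps."""
    rng = np.random.default_rng(seed)
    params = KumParams(rng.uniform(0.4, 3.0), rng.uniform(0.4, 3.0))
    removals = [0] * m
    budget = n - m
    while budget:
        k = int(rng.integers(m))
        removals[k] += 1
        budget -= 1
    scheme = validate_scheme(n, m, removals)
    return generate_pcs2_sample(params, scheme, rng), params


def grid_maximize(objective, bounds=(0.05, 30.0), size: int = 300, refine: int = 2):
    """Independent 2-D grid-search maximizer over log-spaced (alpha, beta).

    Coarse pass over ``bounds`` then ``refine`` zoomed passes around the
    incumbent.  Returns (alpha, beta, value, final grid spacing in log10).
    """
    lo = np.log10(bounds[0])
    hi = np.log10(bounds[1])
    best = None
    for _ in range(refine + 1):
        a_grid = np.logspace(lo, hi, size)
        b_grid = np.logspace(lo, hi, size)
        vals = objective(a_grid[:, None], b_grid[None, :])
        idx = np.unravel_index(np.nanargmax(vals), vals.shape)
        best = (a_grid[idx[0]], b_grid[idx[1]], vals[idx])
        step = (hi - lo) / (size - 1)
        lo_a, hi_a = np.log10(best[0]) - 3 * step, np.log10(best[0]) + 3 * step
        lo_b, hi_b = np.log10(best[1]) - 3 * step, np.log10(best[1]) + 3 * step
        lo, hi = min(lo_a, lo_b), max(hi_a, hi_b)
    return best[0], best[1], best[2], step


def loglik_grid_fn(sample):
    """Vectorized PCS-II log-likelihood over broadcast (alpha, beta) grids."""
    x = sample.observations
    m = sample.m
    R = sample.scheme.removals_array()

    def fn(a, b):
        L = np.log1p(-np.power(x, a[..., None]))  # (A,1,m)
        # sum (b(R+1)-1) log(1-x^a) = b * sum (R+1)L - sum L
        return (
            m * np.log(a)
            + m * np.log(b)
            + (a - 1.0) * np.sum(np.log(x))
            + b * np.sum((R + 1.0) * L, axis=-1)
            - np.sum(L, axis=-1)
        )

    return fn


def mps_grid_fn(sample):
    """Vectorized product-spacings criterion over broadcast grids."""
    x = sample.observations
    R = sample.scheme.removals_array()

    def fn(a, b):
        a3 = a[..., None]
        L = np.log1p(-np.power(x, a3))  # (A,1,m)
        A = b[..., None] * L  # (A,B,m)
        full = np.concatenate(
            [np.zeros(A.shape[:-1] + (1,)), A, np.full(A.shape[:-1] + (1,), -np.inf)],
            axis=-1,
        )
        diffs = full[..., 1:] - full[..., :-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            logsp = full[..., :-1] + np.log(-np.expm1(diffs))
        tail = np.sum(b[..., None] * R * L, axis=-1)
        return np.sum(logsp, axis=-1) + tail

    return fn
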