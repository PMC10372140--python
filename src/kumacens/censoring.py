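"""Progressive Type-II censoring (PCS-II) schemes and sample generation.

A PCS-II life test places ``n`` units on test and observes ``m`` failures.
At the i-th observed failure, ``R_i`` of the surviving units are withdrawn,
so the removal plan must satisfy sum(R) = n - m.  Conventional Type-II
censoring is the special case R = (0, ..., 0, n-m) and the complete sample
is R = 0 with m = n.

Sample generation uses the Balakrishnan-Sandhu transformation: with
W_1..W_m i.i.d. Uniform(0,1) and gamma_i = i + R_m + ... + R_{m-i+1}
(cumulative removals counted from the tail),

    V_i = W_i ** (1/gamma_i),     U_(i) = 1 - V_m * V_{m-1} * ... * V_{m-i+1},

the U_(i) are exactly distributed as the PCS-II uniform order statistics,
and x_(i) = F^{-1}(U_(i)) maps them to the target lifetime distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import KumParams, kum_quantile

__all__ = [
    "CensoringScheme",
    "PCS2Sample",
    "validate_scheme",
    "generate_pcs2_sample",
    "censor_complete_sample",
    "expand_removals",
    "read_scheme",
]


@dataclass(frozen=True)
class CensoringScheme:
    """Removal plan (n, m, R_1..R_m) with sum(R) = n - m, all R_i >= 0."""

    n: int
    m: int
    removals: tuple

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be positive integers")
        if self.m > self.n:
            raise ValueError(f"m={self.m} exceeds n={self.n}")
        R = tuple(int(r) for r in self.removals)
        object.__setattr__(self, "removals", R)
        if len(R) != self.m:
            raise ValueError(f"removals must have length m={self.m}, got {len(R)}")
        if any(r < 0 for r in R):
            raise ValueError("removals must be nonnegative")
        if sum(R) != self.n - self.m:
            raise ValueError(
                f"sum(removals)={sum(R)} must equal n-m={self.n - self.m}"
            )

    @property
    def is_complete(self) -> bool:
        return self.m == self.n

    def removals_array(self) -> np.ndarray:
        return np.asarray(self.removals, dtype=float)


@dataclass(frozen=True)
class PCS2Sample:
    """Ordered censored observations x_(1) < ... < x_(m) bound to a scheme."""

    observations: np.ndarray
    scheme: CensoringScheme

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=float)
        object.__setattr__(self, "observations", obs)
        if obs.ndim != 1 or len(obs) != self.scheme.m:
            raise ValueError(
                f"expected {self.scheme.m} observations, got shape {obs.shape}"
            )
        if np.any((obs <= 0) | (obs >= 1)):
            raise ValueError("observations must lie strictly inside (0, 1)")
        if np.any(np.diff(obs) < 0):
            raise ValueError("observations must be sorted increasingly")

    @property
    def m(self) -> int:
        return self.scheme.m

    @property
    def n(self) -> int:
        return self.scheme.n


def validate_scheme(n: int, m: int, removals) -> CensoringScheme:
    """Validate raw integers into a :class:`CensoringScheme` (or raise)."""
    return CensoringScheme(int(n), int(m), tuple(removals))


def complete_scheme(n: int) -> CensoringScheme:
    """The no-removal scheme with m = n (complete sample)."""
    return CensoringScheme(n, n, (0,) * n)


def generate_pcs2_sample(
    params: KumParams, scheme: CensoringScheme, seed=None
) -> PCS2Sample:
    """Draw one exact-distribution PCS-II sample from Kum(alpha, beta).

    Balakrishnan-Sandhu construction on uniforms, then the Kumaraswamy
    quantile transform.  Reproducible given an integer seed or Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = scheme.m
    R = scheme.removals_array()
    w = rng.uniform(size=m)
    w = np.clip(w, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    # gamma_i = i + R_m + R_{m-1} + ... + R_{m-i+1}
    gam = np.arange(1, m + 1) + np.cumsum(R[::-1])
    logv = np.log(w) / gam  # log V_i
    # U_(i) = 1 - prod_{j=m-i+1}^{m} V_j  => log prod = cumsum of logv from tail
    log_tailprod = np.cumsum(logv[::-1])
    u = -np.expm1(log_tailprod)
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    x = kum_quantile(u, params)
    x = np.maximum.accumulate(x)  # guard monotonicity against rounding
    return PCS2Sample(x, scheme)


def censor_complete_sample(data, scheme: CensoringScheme, seed=None) -> PCS2Sample:
    """Apply a PCS-II removal plan to an observed complete dataset.

    Sequentially records the smallest remaining value as the next failure,
    then withdraws R_i of the remaining units uniformly at random without
    replacement.  Ties are kept in stable sorted order (no jitter).
    """
    data = np.asarray(data, dtype=float)
    if len(data) != scheme.n:
        raise ValueError(f"data length {len(data)} != scheme n={scheme.n}")
    if np.any((data <= 0) | (data >= 1)):
        raise ValueError("data must lie strictly inside (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    remaining = list(np.sort(data, kind="stable"))
    observed = []
    for r_i in scheme.removals:
        observed.append(remaining.pop(0))
        if r_i:
            drop = rng.choice(len(remaining), size=r_i, replace=False)
            remaining = [v for j, v in enumerate(remaining) if j not in set(drop)]
    return PCS2Sample(np.asarray(observed), scheme)


def expand_removals(text: str) -> tuple:
    """Expand run-length shorthand like ``"20,0*19"`` into a removal tuple."""
    out = []
    for tok in str(text).split(","):
        tok = tok.strip()
        if "*" in tok:
            val, count = tok.split("*")
            out.extend([int(val)] * int(count))
        elif tok:
            out.append(int(tok))
    return tuple(out)


def read_scheme(path) -> CensoringScheme:
    """Read a scheme descriptor from JSON or YAML with keys n, m, removals.

    ``removals`` may be a list of integers or the run-length shorthand
    string (e.g. ``"20,0*19"``).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    removals = raw["removals"]
    if isinstance(removals, str):
        removals = expand_removals(removals)
    return validate_scheme(raw["n"], raw["m"], removals)
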