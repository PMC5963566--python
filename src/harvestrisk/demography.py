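"""Collapse life-history parameters into a maximum per-capita growth rate.

The assessment treats demography through a single number: the annual growth
multiplier a population would achieve at low density.  Survival and
reproduction enter through the discrete Euler-Lotka equation

    1 = b * s_juv * s_adult**(alpha - 1) * lam**(-alpha) / (1 - s_adult / lam)

whose unique root above ``s_adult`` is the dominant growth multiplier of the
corresponding age-structured model with geometric adult survival.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InputError

#: Uniform prior bounds for each life-history parameter.
ADULT_SURVIVAL_BOUNDS = (0.95, 0.99)
JUVENILE_SURVIVAL_BOUNDS = (0.5, 0.9)
MATURITY_AGE_BOUNDS = (5, 9)
BIRTH_RATE_BOUNDS = (0.35, 0.65)


@dataclass(frozen=True)
class DemographicParams:
    """Annual adult survival, first-year survival, age at first reproduction,
    and per-capita birth rate (offspring per mature individual per year)."""

    s_adult: float
    s_juv: float
    alpha: int
    b: float

    def __post_init__(self):
        if not (0.0 < self.s_adult < 1.0):
            raise InputError(f"s_adult must lie in (0, 1), got {self.s_adult}")
        if not (0.0 < self.s_juv <= 1.0):
            raise InputError(f"s_juv must lie in (0, 1], got {self.s_juv}")
        if self.alpha < 1:
            raise InputError(f"alpha must be >= 1, got {self.alpha}")
        if self.b < 0:
            raise InputError(f"b must be >= 0, got {self.b}")


def net_reproductive_rate(params: DemographicParams) -> float:
    """Expected lifetime offspring per recruit (R0).

    Sum of b over ages alpha, alpha+1, ... weighted by survivorship
    s_juv * s_adult**(a-1); the geometric tail sums in closed form.
    """
    p = params
    return p.b * p.s_juv * p.s_adult ** (p.alpha - 1) / (1.0 - p.s_adult)


def _euler_lotka_gap(lam, s_adult, s_juv, alpha, b):
    return b * s_juv * s_adult ** (alpha - 1) * lam ** (-alpha) / (1.0 - s_adult / lam) - 1.0


def lambda_max(params: DemographicParams, tol: float = 1e-10) -> float:
    """Dominant annual growth multiplier at low density.

    Bracketed root of the Euler-Lotka equation on (s_adult, inf); with b = 0
    there is no root above s_adult and the population decays at s_adult.
    """
    p = params
    if p.b == 0.0:
        return p.s_adult
    lo = p.s_adult + 1e-12
    hi = max(1.0 + p.b, p.s_adult + 0.5)
    while _euler_lotka_gap(hi, p.s_adult, p.s_juv, p.alpha, p.b) > 0.0:
        hi *= 2.0
    return float(brentq(_euler_lotka_gap, lo, hi,
                        args=(p.s_adult, p.s_juv, p.alpha, p.b), xtol=tol))


def lambda_max_many(s_adult, s_juv, alpha, b, iters: int = 200) -> np.ndarray:
    """Vectorised Euler-Lotka root by bisection over parameter arrays.

    200 bisection steps drive the bracket width far below 1e-10, matching
    the scalar solver to full float precision.
    """
    s_adult = np.asarray(s_adult, dtype=float)
    s_juv = np.asarray(s_juv, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    b = np.asarray(b, dtype=float)
    shape = np.broadcast_shapes(s_adult.shape, s_juv.shape, alpha.shape, b.shape)
    s_adult, s_juv, alpha, b = np.broadcast_arrays(s_adult, s_juv, alpha, b)

    lo = s_adult + 1e-12
    hi = np.maximum(1.0 + b, s_adult + 0.5)
    alive = b > 0.0
    with np.errstate(divide="ignore", over="ignore"):
        for _ in range(100):  # expand brackets where the root lies above hi
            gap = _euler_lotka_gap(hi, s_adult, s_juv, alpha, b)
            grow = alive & (gap > 0.0)
            if not np.any(grow):
                break
            hi = np.where(grow, hi * 2.0, hi)
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            above = _euler_lotka_gap(mid, s_adult, s_juv, alpha, b) > 0.0
            lo = np.where(above, mid, lo)
            hi = np.where(above, hi, mid)
    root = 0.5 * (lo + hi)
    out = np.where(alive, root, s_adult)
    return out.reshape(shape)


def rmax(params: DemographicParams) -> float:
    """Maximum per-capita growth rate: lambda_max - 1."""
    return lambda_max(params) - 1.0
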