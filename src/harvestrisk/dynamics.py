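"""Density-regulated single-stock projection with annual removals.

Generalized-logistic (Pella-Tomlinson) surplus production:

    N' = max(0, N + N * rmax * (1 - (N / K)**theta) - removals)

Demographic detail enters only through ``rmax``; zero abundance is
absorbing.  The default shape ``theta = 2.39`` puts the maximum of surplus
production near 0.6 K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catch_history import RemovalsSeries
from .errors import ForcingGapError, InputError

DEFAULT_THETA = 2.39

#: Habitat-based ceiling on carrying capacity (animals).
K_CAP = 5000.0


@dataclass(frozen=True)
class DynamicsParams:
    rmax: float
    K: float
    theta: float = DEFAULT_THETA
    N_start: float | None = None
    start_year: int = 1900

    def __post_init__(self):
        if self.rmax <= -1.0:
            raise InputError(f"rmax must exceed -1, got {self.rmax}")
        if self.K <= 0:
            raise InputError(f"K must be positive, got {self.K}")
        if self.theta <= 0:
            raise InputError(f"theta must be positive, got {self.theta}")
        if self.N_start is not None and not (0.0 < self.N_start <= self.K):
            raise InputError(
                f"N_start must lie in (0, K]; got {self.N_start} with K={self.K}"
            )


class Trajectory:
    """Abundance by year; one more entry than the forcing that produced it."""

    def __init__(self, years, N):
        years = np.asarray(years, dtype=int)
        N = np.asarray(N, dtype=float)
        if years.size != N.size:
            raise InputError("years and N differ in length")
        if np.any(N < 0):
            raise InputError("abundance must be non-negative")
        self.years = years
        self.N = N

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def abundance_at(self, year: int) -> float:
        if not (self.start_year <= year <= self.end_year):
            raise KeyError(f"year {year} outside trajectory [{self.start_year}, {self.end_year}]")
        return float(self.N[year - self.start_year])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "N": self.N})

    def __len__(self) -> int:
        return self.years.size


def surplus(N, rmax, K, theta):
    """Annual surplus production at abundance N (vectorised)."""
    N = np.asarray(N, dtype=float)
    out = N * rmax * (1.0 - (N / K) ** theta)
    return float(out) if out.ndim == 0 else out


def step(N, params: DynamicsParams, removals: float):
    """One annual update; clamped at zero, which is absorbing."""
    if np.any(np.asarray(N) < 0):
        raise InputError("abundance must be non-negative")
    if np.any(np.asarray(removals) < 0):
        raise InputError("removals must be non-negative")
    out = np.maximum(0.0, N + surplus(N, params.rmax, params.K, params.theta) - removals)
    return float(out) if np.ndim(out) == 0 else out


def simulate(params: DynamicsParams, removals: RemovalsSeries) -> Trajectory:
    """Iterate the annual update over the removals series.

    The trajectory starts at ``params.N_start`` in ``params.start_year`` and
    ends one year after the last removal.  Deterministic given inputs.
    """
    if params.N_start is None:
        raise InputError("simulate requires N_start")
    if removals.start_year != params.start_year:
        raise ForcingGapError(
            f"removals start in {removals.start_year} but the simulation "
            f"starts in {params.start_year}"
        )
    n_years = len(removals)
    N = np.empty(n_years + 1)
    N[0] = params.N_start
    for i in range(n_years):
        N[i + 1] = step(N[i], params, removals.removals[i])
    years = np.arange(params.start_year, params.start_year + n_years + 1)
    return Trajectory(years, N)


def msyl_fraction(theta: float) -> float:
    """Depletion level (fraction of K) at which surplus production peaks.

    d/dN [N rmax (1 - (N/K)^theta)] = 0  =>  N*/K = (1 + theta)**(-1/theta).
    """
    if theta <= 0:
        raise InputError(f"theta must be positive, got {theta}")
    return (1.0 + theta) ** (-1.0 / theta)
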