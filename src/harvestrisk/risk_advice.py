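"""Forward projection under candidate catches and risk-based quota advice.

Each posterior draw is projected a fixed horizon under a constant annual
catch; the weighted fraction of draws that end strictly above their starting
abundance is the probability of increase.  The advised quota is the largest
catch on the grid meeting the probability criterion (default: at least 70%
probability of increase over 5 years).  Subsistence-demand arithmetic for
dog-team provisioning lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .inference import PosteriorEnsemble

DEFAULT_HORIZON = 5
DEFAULT_CRITERION = 0.70


def _default_grid() -> tuple[int, ...]:
    return tuple(range(0, 201))


@dataclass(frozen=True)
class ProjectionSpec:
    horizon: int = DEFAULT_HORIZON
    criterion: float = DEFAULT_CRITERION
    catch_grid: tuple[int, ...] = field(default_factory=_default_grid)
    #: struck-and-lost fraction applied to future catches (default: quotas
    #: bind landed animals, so none)
    future_loss_rate: float = 0.0

    def __post_init__(self):
        if self.horizon < 1:
            raise InputError(f"horizon must be >= 1, got {self.horizon}")
        if not (0.0 < self.criterion <= 1.0):
            raise InputError(f"criterion must lie in (0, 1], got {self.criterion}")
        if any(c < 0 for c in self.catch_grid):
            raise InputError("catch grid must be non-negative")
        if not (0.0 <= self.future_loss_rate < 1.0):
            raise InputError(f"future_loss_rate must lie in [0, 1), got {self.future_loss_rate}")


@dataclass
class RiskCurve:
    """Probability of increase at each evaluated catch level."""

    catches: np.ndarray
    p_increase: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return {int(c): float(p) for c, p in zip(self.catches, self.p_increase)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"catch": self.catches, "p_increase": self.p_increase})


@dataclass(frozen=True)
class QuotaAdvice:
    quota: int
    criterion: float
    horizon: int
    curve: RiskCurve


@dataclass(frozen=True)
class DemandParams:
    """Community dog-team provisioning: full-time hunters, annual walrus need
    per hunter, and the (documentary) team size behind that need."""

    n_hunters: int
    walruses_per_hunter_year: int = 12
    dogs_per_team: int = 16

    def __post_init__(self):
        if min(self.n_hunters, self.walruses_per_hunter_year, self.dogs_per_team) < 0:
            raise InputError("demand parameters must be non-negative")


def _project_endpoints(ensemble: PosteriorEnsemble, catch: float,
                       spec: ProjectionSpec) -> tuple[np.ndarray, np.ndarray]:
    df = ensemble.draws
    N0 = df["N_current"].to_numpy()
    rmax = df["rmax"].to_numpy()
    K = df["K"].to_numpy()
    theta = df["theta"].to_numpy()
    removal = catch / (1.0 - spec.future_loss_rate)
    N = N0.copy()
    for _ in range(spec.horizon):
        N = np.maximum(0.0, N + N * rmax * (1.0 - (N / K) ** theta) - removal)
    return N0, N


def prob_increase(ensemble: PosteriorEnsemble, catch: float,
                  spec: ProjectionSpec = ProjectionSpec()) -> float:
    """Weighted probability that abundance after the horizon strictly exceeds
    each draw's starting abundance, under a constant annual catch."""
    if catch < 0:
        raise InputError(f"catch must be non-negative, got {catch}")
    N0, N = _project_endpoints(ensemble, catch, spec)
    return float(np.sum(ensemble.weights[N > N0]))


def risk_curve(ensemble: PosteriorEnsemble,
               spec: ProjectionSpec = ProjectionSpec()) -> RiskCurve:
    """Evaluate prob_increase across the catch grid on one shared ensemble.

    Dynamics are deterministic per draw, so the curve is exactly
    non-increasing in catch.
    """
    if len(spec.catch_grid) == 0:
        raise InputError("catch grid is empty")
    catches = np.asarray(sorted(spec.catch_grid))
    p = np.array([prob_increase(ensemble, float(c), spec) for c in catches])
    return RiskCurve(catches=catches, p_increase=p)


def advise_quota(ensemble: PosteriorEnsemble,
                 spec: ProjectionSpec = ProjectionSpec()) -> QuotaAdvice:
    """Largest grid catch whose probability of increase meets the criterion
    (0 if none does)."""
    if 0 not in spec.catch_grid:
        raise InputError("catch grid must include 0")
    curve = risk_curve(ensemble, spec)
    ok = curve.p_increase >= spec.criterion
    quota = int(curve.catches[ok][-1]) if np.any(ok) else 0
    return QuotaAdvice(quota=quota, criterion=spec.criterion,
                       horizon=spec.horizon, curve=curve)


def per_hunter_annual_need(months_per_walrus: float = 1.0,
                           months_per_year: int = 12) -> float:
    """Walruses one hunter needs per year if one walrus feeds the dog team
    for ``months_per_walrus`` months."""
    if months_per_walrus <= 0:
        raise InputError("months_per_walrus must be positive")
    return months_per_year / months_per_walrus


def subsistence_demand(params: DemandParams) -> int:
    """Annual community walrus demand: hunters times per-hunter need."""
    return params.n_hunters * params.walruses_per_hunter_year


def demand_gap(demand: int, quota: int) -> int:
    """Signed shortfall: demand minus quota (positive when the quota falls
    short of demand)."""
    if demand < 0 or quota < 0:
        raise InputError("demand and quota must be non-negative")
    return demand - quota
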