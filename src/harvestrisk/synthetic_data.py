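"""Known-truth scenario generation for end-to-end testing.

Builds removal series from simple catch policies, simulates the true
trajectory, adds log-normal survey noise, and degrades complete removal
series into sparse reported-catch records so reconstruction can be
round-trip tested.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from . import demography, dynamics
from .catch_history import (
    LossSchedule,
    RemovalsSeries,
    ReportedCatch,
    loss_rate,
)
from .dynamics import DynamicsParams, Trajectory
from .errors import InputError
from .inference import SurveyObservation, lognormal_sigma2


@dataclass(frozen=True)
class ConstantCatch:
    """The same number of removals every year."""

    level: float

    def __call__(self, N: float, year: int) -> float:
        return self.level


@dataclass(frozen=True)
class ProportionalCatch:
    """Removals as a fixed fraction of current abundance."""

    rate: float

    def __call__(self, N: float, year: int) -> float:
        return self.rate * N


CatchPolicy = Union[ConstantCatch, ProportionalCatch]


@dataclass(frozen=True)
class ScenarioConfig:
    """Truth parameters and observation design for one synthetic scenario."""

    seed: int
    demographics: demography.DemographicParams
    K: float
    d0: float
    start_year: int
    end_year: int
    policy: CatchPolicy
    survey_years: tuple[int, ...] = ()
    survey_cvs: tuple[float, ...] = ()
    theta: float = dynamics.DEFAULT_THETA
    missing_fraction: float = 0.3

    def __post_init__(self):
        if not (0.0 < self.d0 <= 1.0):
            raise InputError(f"d0 must lie in (0, 1], got {self.d0}")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise InputError(f"missing_fraction must lie in [0, 1), got {self.missing_fraction}")
        if self.start_year > self.end_year:
            raise InputError("start_year must not exceed end_year")
        if len(self.survey_years) != len(self.survey_cvs):
            raise InputError("survey_years and survey_cvs differ in length")

    @property
    def dynamics_params(self) -> DynamicsParams:
        return DynamicsParams(
            rmax=demography.rmax(self.demographics),
            K=self.K,
            theta=self.theta,
            N_start=self.d0 * self.K,
            start_year=self.start_year,
        )


def generate_truth(config: ScenarioConfig) -> tuple[Trajectory, RemovalsSeries]:
    """Run the catch policy against the true dynamics.

    Returns the trajectory and the removal series it implies.  If the policy
    drives the stock extinct before the range ends a warning is emitted and
    the (partly zero) trajectory is still returned.
    """
    params = config.dynamics_params
    years = np.arange(config.start_year, config.end_year + 1)
    removals = np.empty(years.size)
    N = params.N_start
    for i, year in enumerate(years):
        removals[i] = config.policy(N, int(year))
        N = dynamics.step(N, params, removals[i])
    series = RemovalsSeries(years, removals)
    traj = dynamics.simulate(params, series)
    if traj.N[-1] == 0.0:
        warnings.warn(
            f"catch policy drove the stock extinct before {config.end_year}",
            stacklevel=2,
        )
    return traj, series


def generate_surveys(
    traj: Trajectory,
    years: Sequence[int],
    cvs: Union[float, Sequence[float]],
    seed: int,
) -> list[SurveyObservation]:
    """Log-normally noisy abundance estimates of the trajectory.

    estimate = N * exp(eps), eps ~ Normal(-sigma2/2, sigma2) with
    sigma2 = log(1 + cv^2): mean-unbiased in natural space.
    """
    years = list(years)
    if np.isscalar(cvs):
        cvs = [float(cvs)] * len(years)
    if len(cvs) != len(years):
        raise InputError("years and cvs differ in length")
    rng = np.random.default_rng(seed)
    out = []
    for year, cv in zip(years, cvs):
        n = traj.abundance_at(year)
        sigma2 = lognormal_sigma2(cv)
        eps = rng.normal(-0.5 * sigma2, np.sqrt(sigma2))
        out.append(SurveyObservation(year=int(year), estimate=n * np.exp(eps), cv=float(cv)))
    return out


def degrade_catch_record(
    removals: RemovalsSeries,
    missing_fraction: float,
    seed: int,
    schedule: LossSchedule = LossSchedule(),
    underreport_factor: float = 1.0,
    era_boundary: int = 1993,
) -> list[ReportedCatch]:
    """Turn a complete removals series into a sparse reported-catch record.

    Removals are converted back to landed counts via the inverse of the loss
    correction, then a seeded mask hides ``missing_fraction`` of years as
    undocumented, so reconstruction with the true schedule round-trips.
    """
    if not (0.0 <= missing_fraction < 1.0):
        raise InputError(f"missing_fraction must lie in [0, 1), got {missing_fraction}")
    rng = np.random.default_rng(seed)
    masked = rng.random(len(removals)) < missing_fraction
    landed = removals.removals * (1.0 - loss_rate(removals.years, schedule)) / underreport_factor
    out = []
    for year, value, hide in zip(removals.years, landed, masked):
        source = "HLG" if year < era_boundary else "Piniarneq"
        if hide:
            out.append(ReportedCatch(year=int(year), landed=None, documented=False, source=source))
        else:
            out.append(ReportedCatch(year=int(year), landed=float(value), documented=True, source=source))
    return out
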