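"""Condition the dynamics on abundance surveys by prior sampling and
importance weighting (sampling-importance-resampling, SIR).

Parameters are drawn from independent uniform priors, each draw is simulated
through the removals history, and draws are weighted by the log-normal
likelihood of the survey estimates.  An optional equal-weight resample
collapses the weighted cloud to an ensemble ready for projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from . import demography
from .catch_history import RemovalsSeries
from .dynamics import DEFAULT_THETA, K_CAP, Trajectory
from .errors import CoverageError, DegeneratePosteriorError, InputError


@dataclass(frozen=True)
class SurveyObservation:
    """An abundance point estimate with its coefficient of variation."""

    year: int
    estimate: float
    cv: float

    def __post_init__(self):
        if self.estimate <= 0:
            raise InputError(f"survey {self.year}: estimate must be > 0, got {self.estimate}")
        if self.cv <= 0:
            raise InputError(f"survey {self.year}: cv must be > 0, got {self.cv}")


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds for every sampled parameter.

    ``theta`` may be a fixed float or a (lo, hi) range.  ``d0`` is the
    initial depletion N_start / K.  ``K`` bounds honour the habitat cap.
    """

    s_adult: tuple[float, float] = demography.ADULT_SURVIVAL_BOUNDS
    s_juv: tuple[float, float] = demography.JUVENILE_SURVIVAL_BOUNDS
    alpha: tuple[int, int] = demography.MATURITY_AGE_BOUNDS
    b: tuple[float, float] = demography.BIRTH_RATE_BOUNDS
    K: tuple[float, float] = (500.0, K_CAP)
    d0: tuple[float, float] = (0.3, 1.0)
    theta: Union[float, tuple[float, float]] = DEFAULT_THETA

    def __post_init__(self):
        for name in ("s_adult", "s_juv", "alpha", "b", "K", "d0"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise InputError(f"prior {name}: invalid bounds ({lo}, {hi})")
        if self.K[1] > K_CAP:
            raise InputError(f"K upper bound {self.K[1]} exceeds the habitat cap {K_CAP}")


@dataclass
class PosteriorEnsemble:
    """Weighted parameter draws after conditioning on surveys.

    ``draws`` has one row per draw with columns
    s_adult, s_juv, alpha, b, rmax, K, theta, d0, N_start, N_current;
    ``ess`` is the effective sample size of the importance stage.
    """

    draws: pd.DataFrame
    weights: np.ndarray
    ess: float
    seed: int | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.draws) != self.weights.size:
            raise InputError("draws and weights differ in length")
        if len(self.draws) == 0:
            raise InputError("ensemble is empty")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise InputError("weights must sum to 1")
        if not (0 < self.ess <= len(self.draws) + 1e-9):
            raise InputError(f"ess {self.ess} outside (0, n_draws]")

    def __len__(self) -> int:
        return len(self.draws)

    def weighted_mean(self, column: str) -> float:
        return float(np.sum(self.weights * self.draws[column].to_numpy()))

    def weighted_std(self, column: str) -> float:
        x = self.draws[column].to_numpy()
        mu = np.sum(self.weights * x)
        return float(np.sqrt(np.sum(self.weights * (x - mu) ** 2)))


def lognormal_sigma2(cv) -> float:
    """Log-scale variance implied by a coefficient of variation."""
    return np.log1p(np.asarray(cv, dtype=float) ** 2)


def log_likelihood(traj: Trajectory, surveys: Sequence[SurveyObservation]) -> float:
    """Sum of log-normal survey log-densities against the trajectory.

    Each survey contributes the density of log(estimate) under
    Normal(log(N_year), log(1 + cv^2)); a zero prediction gives -inf.
    """
    total = 0.0
    for s in surveys:
        if not (traj.start_year <= s.year <= traj.end_year):
            raise CoverageError(
                f"survey year {s.year} outside trajectory [{traj.start_year}, {traj.end_year}]"
            )
        n = traj.abundance_at(s.year)
        if n == 0.0:
            return float("-inf")
        sd = np.sqrt(lognormal_sigma2(s.cv))
        total += norm.logpdf(np.log(s.estimate), loc=np.log(n), scale=sd)
    return float(total)


def sample_priors(priors: PriorSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n parameter vectors from the independent uniform priors.

    Column order fixes the RNG consumption order, so identical seeds give
    identical draws.
    """
    cols = {
        "s_adult": rng.uniform(*priors.s_adult, n),
        "s_juv": rng.uniform(*priors.s_juv, n),
        "alpha": rng.integers(priors.alpha[0], priors.alpha[1] + 1, n),
        "b": rng.uniform(*priors.b, n),
        "K": rng.uniform(*priors.K, n),
        "d0": rng.uniform(*priors.d0, n),
    }
    if isinstance(priors.theta, tuple):
        cols["theta"] = rng.uniform(*priors.theta, n)
    else:
        cols["theta"] = np.full(n, float(priors.theta))
    df = pd.DataFrame(cols)
    df["rmax"] = demography.lambda_max_many(
        df["s_adult"], df["s_juv"], df["alpha"], df["b"]
    ) - 1.0
    df["N_start"] = df["d0"] * df["K"]
    return df


def _simulate_batch(df: pd.DataFrame, removals: RemovalsSeries,
                    survey_years: Sequence[int]) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Simulate every draw through the forcing at once.

    Returns terminal abundance per draw and the abundance each survey year.
    """
    N = df["N_start"].to_numpy().copy()
    rmax = df["rmax"].to_numpy()
    K = df["K"].to_numpy()
    theta = df["theta"].to_numpy()
    wanted = set(int(y) for y in survey_years)
    at_year: dict[int, np.ndarray] = {}
    for i, year in enumerate(removals.years):
        if year in wanted:
            at_year[int(year)] = N.copy()
        N = np.maximum(0.0, N + N * rmax * (1.0 - (N / K) ** theta) - removals.removals[i])
    terminal_year = removals.end_year + 1
    if terminal_year in wanted:
        at_year[terminal_year] = N.copy()
    return N, at_year


def fit_sir(
    priors: PriorSpec,
    removals: RemovalsSeries,
    surveys: Sequence[SurveyObservation],
    n_draws: int,
    resample: int | None = None,
    seed: int = 0,
) -> PosteriorEnsemble:
    """Sampling-importance-resampling fit of the dynamics to surveys.

    Draws from ``priors``, simulates each draw under ``removals`` from the
    series start, weights by the survey likelihood, and (optionally)
    resamples ``resample`` equally weighted draws.  Deterministic given
    ``seed``.
    """
    if not surveys:
        raise InputError("at least one survey is required; use sample_priors for "
                         "a prior-only ensemble")
    if resample is not None and not (1 <= resample <= n_draws):
        raise InputError(f"resample must lie in [1, n_draws], got {resample}")
    lo, hi = removals.start_year, removals.end_year + 1
    for s in surveys:
        if not (lo <= s.year <= hi):
            raise CoverageError(f"survey year {s.year} outside simulated span [{lo}, {hi}]")

    rng = np.random.default_rng(seed)
    df = sample_priors(priors, n_draws, rng)
    terminal, at_year = _simulate_batch(df, removals, [s.year for s in surveys])
    df["N_current"] = terminal

    loglik = np.zeros(n_draws)
    for s in surveys:
        n = at_year[s.year]
        sd = np.sqrt(lognormal_sigma2(s.cv))
        with np.errstate(divide="ignore"):
            term = np.where(
                n > 0.0,
                norm.logpdf(np.log(s.estimate), loc=np.log(np.where(n > 0, n, 1.0)), scale=sd),
                -np.inf,
            )
        loglik += term

    lse = logsumexp(loglik)
    if not np.isfinite(lse):
        raise DegeneratePosteriorError(
            "every prior draw has zero survey likelihood; increase n_draws or widen priors"
        )
    weights = np.exp(loglik - lse)
    weights /= weights.sum()
    ess = float(1.0 / np.sum(weights**2))

    if resample is not None:
        idx = rng.choice(n_draws, size=resample, replace=True, p=weights)
        df = df.iloc[idx].reset_index(drop=True)
        weights = np.full(resample, 1.0 / resample)
    return PosteriorEnsemble(draws=df, weights=weights, ess=ess, seed=seed)


def prior_ensemble(priors: PriorSpec, removals: RemovalsSeries, n_draws: int,
                   seed: int = 0) -> PosteriorEnsemble:
    """Equal-weight prior-predictive ensemble (no survey conditioning)."""
    rng = np.random.default_rng(seed)
    df = sample_priors(priors, n_draws, rng)
    terminal, _ = _simulate_batch(df, removals, [])
    df["N_current"] = terminal
    w = np.full(n_draws, 1.0 / n_draws)
    return PosteriorEnsemble(draws=df, weights=w, ess=float(n_draws), seed=seed)
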