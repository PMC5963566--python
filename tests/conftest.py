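import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from harvestrisk import demography, inference, synthetic_data
from harvestrisk.catch_history import LossSchedule, ReconstructionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def demo_params():
    return demography.DemographicParams(s_adult=0.97, s_juv=0.7, alpha=7, b=0.5)


@pytest.fixture
def default_schedule():
    return LossSchedule()


@pytest.fixture
def default_recon():
    return ReconstructionConfig()


def sample_demographics(rng, n):
    """Random draws from the default life-history prior ranges."""
    lo, hi = demography.ADULT_SURVIVAL_BOUNDS
    s_adult = rng.uniform(lo, hi, n)
    lo, hi = demography.JUVENILE_SURVIVAL_BOUNDS
    s_juv = rng.uniform(lo, hi, n)
    lo, hi = demography.MATURITY_AGE_BOUNDS
    alpha = rng.integers(lo, hi + 1, n)
    lo, hi = demography.BIRTH_RATE_BOUNDS
    b = rng.uniform(lo, hi, n)
    return s_adult, s_juv, alpha, b


@pytest.fixture(scope="session")
def base_scenario():
    """A known-truth scenario shared across inference/risk tests."""
    demo = demography.DemographicParams(s_adult=0.97, s_juv=0.7, alpha=6, b=0.45)
    return synthetic_data.ScenarioConfig(
        seed=7,
        demographics=demo,
        K=4000.0,
        d0=0.8,
        start_year=1900,
        end_year=2015,
        policy=synthetic_data.ConstantCatch(60.0),
        survey_years=(1995, 2000, 2005, 2010, 2015),
        survey_cvs=(0.05,) * 5,
    )


@pytest.fixture(scope="session")
def base_truth(base_scenario):
    return synthetic_data.generate_truth(base_scenario)


@pytest.fixture(scope="session")
def base_surveys(base_scenario, base_truth):
    traj, _ = base_truth
    return synthetic_data.generate_surveys(
        traj, base_scenario.survey_years, list(base_scenario.survey_cvs),
        base_scenario.seed,
    )


@pytest.fixture(scope="session")
def fitted_ensemble(base_truth, base_surveys):
    """Moderate-size SIR fit reused by projection and advice tests."""
    _, removals = base_truth
    return inference.fit_sir(
        inference.PriorSpec(), removals, base_surveys,
        n_draws=4000, resample=800, seed=11,
    )
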