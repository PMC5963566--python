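"""Independent oracles used to cross-check the package implementation.

Everything here is deliberately brute force and shares no code with the
package: truncated life-table sums, an explicit age-structured projection
matrix, explicit enumeration fills, and hand-written density formulas.
"""

from __future__ import annotations

import math

import numpy as np


def r0_truncated_sum(s_adult, s_juv, alpha, b, max_age=500):
    """Lifetime offspring per recruit by explicit summation over ages."""
    total = 0.0
    for age in range(alpha, max_age + 1):
        survivorship = s_juv * s_adult ** (age - 1)
        total += b * survivorship
    return total


def leslie_lambda(s_adult, s_juv, alpha, b, max_age=200):
    """Dominant eigenvalue of the explicit age-structured projection matrix.

    Pre-breeding census with classes for ages 1..max_age; the oldest class
    is a self-looping plus-group, so geometric adult survival is represented
    without truncation error.
    """
    A = max_age
    M = np.zeros((A, A))
    M[0, alpha - 1 :] = s_juv * b  # column a-1 holds age-a parents
    for i in range(A - 1):
        M[i + 1, i] = s_adult
    M[A - 1, A - 1] = s_adult  # plus-group
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def fill_by_enumeration(documented, year, window):
    """Mean of the `window` most recent documented years before `year`.

    `documented` maps year -> landed; `window` is an int or "all".
    """
    prior = sorted(y for y in documented if y < year)
    if window != "all":
        prior = prior[-window:]
    values = [documented[y] for y in prior]
    return sum(values) / len(values)


def lognormal_survey_logpdf(estimate, prediction, cv):
    """Hand-written log-density of log(estimate) ~ N(log(prediction), log(1+cv^2))."""
    sigma2 = math.log(1.0 + cv * cv)
    z = math.log(estimate) - math.log(prediction)
    return -0.5 * math.log(2.0 * math.pi * sigma2) - z * z / (2.0 * sigma2)


def step_once(N, rmax, K, theta, removals):
    """One generalized-logistic update, written independently."""
    growth = N * rmax * (1.0 - (N / K) ** theta)
    return max(0.0, N + growth - removals)


def production_grid_peak(rmax, K, theta, n_grid=200_001):
    """Abundance maximizing surplus production, found by brute-force grid."""
    N = np.linspace(0.0, K, n_grid)
    production = N * rmax * (1.0 - (N / K) ** theta)
    return float(N[np.argmax(production)])
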