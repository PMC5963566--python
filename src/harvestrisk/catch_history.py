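"""Reconstruction of total removals from sparse, era-heterogeneous catch records.

Reported landed catches are incomplete: whole years are missing, and hunting
losses (animals struck but never retrieved) changed with the shift from
harpoon-first hunting to motorboats.  This module fills missing years from
the mean of preceding documented years, applies a piecewise-linear
struck-and-lost schedule, and scales for underreporting, producing the
complete removals series that forces the population model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InputError, UnfillableRangeError

SOURCES = ("HLG", "Piniarneq", "detailed_report", "special_report")

#: First year of the modern (Piniarneq) reporting era; fills do not mix eras.
ERA_BOUNDARY = 1993


@dataclass(frozen=True)
class ReportedCatch:
    """One year's reported landed catch.

    ``documented`` is False exactly when no landed count exists for the year.
    """

    year: int
    landed: float | None
    documented: bool
    source: str = "special_report"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise InputError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.documented:
            if self.landed is None:
                raise InputError(f"year {self.year}: documented record lacks a landed count")
            if self.landed < 0:
                raise InputError(f"year {self.year}: landed count {self.landed} is negative")
        elif self.landed is not None:
            raise InputError(f"year {self.year}: undocumented record carries a landed count")


@dataclass(frozen=True)
class LossSchedule:
    """Struck-and-lost fraction by year: low before motorboats, high after.

    The rate is ``early_rate`` before ``ramp_start``, ``late_rate`` from
    ``ramp_end`` onwards, and linearly interpolated in between.
    """

    early_rate: float = 0.05
    late_rate: float = 0.30
    ramp_start: int = 1960
    ramp_end: int = 1970

    def __post_init__(self):
        if not (0.0 <= self.early_rate <= self.late_rate < 1.0):
            raise InputError(
                f"loss rates must satisfy 0 <= early ({self.early_rate}) "
                f"<= late ({self.late_rate}) < 1"
            )
        if self.ramp_start > self.ramp_end:
            raise InputError(f"ramp_start {self.ramp_start} > ramp_end {self.ramp_end}")


@dataclass(frozen=True)
class ReconstructionConfig:
    """How to fill missing years and correct for underreporting.

    ``fill_window``: number of most recent documented years to average when
    filling a gap, or ``"all"`` for every preceding documented year in the
    same reporting era.  ``underreport_factor`` multiplies landed counts
    (>= 1; the default 1.0 applies no correction).
    """

    fill_window: Union[int, str] = "all"
    underreport_factor: float = 1.0
    era_boundary: int = ERA_BOUNDARY

    def __post_init__(self):
        if self.fill_window != "all":
            if not isinstance(self.fill_window, int) or self.fill_window < 1:
                raise InputError(f"fill_window must be 'all' or an integer >= 1, got {self.fill_window!r}")
        if self.underreport_factor < 1.0:
            raise InputError(f"underreport_factor must be >= 1, got {self.underreport_factor}")


@dataclass(frozen=True)
class LandedRecord:
    """A landed value for one year, flagged if it was extrapolated."""

    year: int
    landed: float
    extrapolated: bool


class RemovalsSeries:
    """Contiguous per-year total removals (landed equivalents incl. losses).

    Provenance flags mark years whose landed value was extrapolated rather
    than documented.
    """

    def __init__(self, years, removals, extrapolated=None):
        years = np.asarray(years, dtype=int)
        removals = np.asarray(removals, dtype=float)
        if years.size == 0:
            raise InputError("removals series is empty")
        if years.size != removals.size:
            raise InputError("years and removals differ in length")
        if not np.array_equal(years, np.arange(years[0], years[0] + years.size)):
            raise InputError("removals series must cover contiguous years")
        if np.any(removals < 0):
            raise InputError("removals must be non-negative")
        if extrapolated is None:
            extrapolated = np.zeros(years.size, dtype=bool)
        self.years = years
        self.removals = removals
        self.extrapolated = np.asarray(extrapolated, dtype=bool)

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def __len__(self) -> int:
        return self.years.size

    def value(self, year: int) -> float:
        if not (self.start_year <= year <= self.end_year):
            raise KeyError(f"year {year} outside removals range "
                           f"[{self.start_year}, {self.end_year}]")
        return float(self.removals[year - self.start_year])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "removals": self.removals, "extrapolated": self.extrapolated}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RemovalsSeries":
        extrap = df["extrapolated"] if "extrapolated" in df else None
        return cls(df["year"].to_numpy(), df["removals"].to_numpy(), extrap)

    def __eq__(self, other):
        return (
            isinstance(other, RemovalsSeries)
            and np.array_equal(self.years, other.years)
            and np.array_equal(self.removals, other.removals)
            and np.array_equal(self.extrapolated, other.extrapolated)
        )


def _check_unique_years(series: Sequence[ReportedCatch]) -> None:
    years = [r.year for r in series]
    if len(set(years)) != len(years):
        dupes = sorted({y for y in years if years.count(y) > 1})
        raise InputError(f"duplicate years in catch series: {dupes}")


def _era(year: int, boundary: int) -> int:
    return 0 if year < boundary else 1


def fill_missing_years(
    series: Sequence[ReportedCatch],
    config: ReconstructionConfig,
    year_range: tuple[int, int],
) -> list[LandedRecord]:
    """Produce a landed value for every year in ``year_range``.

    Documented values are preserved unchanged.  Each missing year is filled
    with the arithmetic mean of the ``fill_window`` most recent documented
    years that precede it within the same reporting era (falling back to any
    preceding documented year if the era has none).  Filled values are
    flagged ``extrapolated``.
    """
    _check_unique_years(series)
    start, end = year_range
    if start > end:
        raise InputError(f"empty year range [{start}, {end}]")
    documented = {r.year: float(r.landed) for r in series if r.documented}

    out: list[LandedRecord] = []
    for year in range(start, end + 1):
        if year in documented:
            out.append(LandedRecord(year, documented[year], extrapolated=False))
            continue
        prior = sorted(y for y in documented if y < year)
        same_era = [y for y in prior if _era(y, config.era_boundary) == _era(year, config.era_boundary)]
        pool = same_era if same_era else prior
        if not pool:
            raise UnfillableRangeError(
                f"year {year}: no documented year precedes it; cannot fill"
            )
        if config.fill_window != "all":
            pool = pool[-config.fill_window:]
        fill = float(np.mean([documented[y] for y in pool]))
        out.append(LandedRecord(year, fill, extrapolated=True))
    return out


def loss_rate(year, schedule: LossSchedule):
    """Struck-and-lost fraction for ``year`` (scalar or array).

    Piecewise: ``early_rate`` before the ramp, ``late_rate`` after it,
    linear in between; non-decreasing and continuous at the endpoints.
    """
    if schedule.ramp_start == schedule.ramp_end:
        rate = np.where(np.asarray(year) < schedule.ramp_start,
                        schedule.early_rate, schedule.late_rate)
    else:
        rate = np.interp(
            year,
            [schedule.ramp_start, schedule.ramp_end],
            [schedule.early_rate, schedule.late_rate],
        )
    return float(rate) if np.isscalar(year) else rate


def to_removals(landed, year, schedule: LossSchedule, config: ReconstructionConfig):
    """Convert landed catch to total removals.

    Losses are a fraction of all animals struck, so landed catch is the
    surviving fraction: removals = landed * factor / (1 - loss_rate).
    """
    landed = np.asarray(landed, dtype=float)
    if np.any(landed < 0):
        raise InputError("landed must be non-negative")
    out = landed * config.underreport_factor / (1.0 - loss_rate(year, schedule))
    return float(out) if out.ndim == 0 else out


def reconstruct(
    series: Sequence[ReportedCatch],
    schedule: LossSchedule,
    config: ReconstructionConfig,
    year_range: tuple[int, int],
) -> RemovalsSeries:
    """Fill missing years, then correct every year for underreporting and losses."""
    filled = fill_missing_years(series, config, year_range)
    years = np.array([r.year for r in filled])
    landed = np.array([r.landed for r in filled])
    extrapolated = np.array([r.extrapolated for r in filled])
    removals = to_removals(landed, years, schedule, config)
    return RemovalsSeries(years, removals, extrapolated)
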