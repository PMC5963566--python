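"""CSV and YAML formats for catches, surveys, removals, posteriors, and the
assessment configuration.  Every writer/reader pair is a lossless round trip
on valid data."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .catch_history import (
    LossSchedule,
    ReconstructionConfig,
    RemovalsSeries,
    ReportedCatch,
    SOURCES,
)
from .errors import ParseError
from .inference import PosteriorEnsemble, PriorSpec, SurveyObservation
from .risk_advice import ProjectionSpec

CATCH_COLUMNS = ["year", "landed", "documented", "source"]
SURVEY_COLUMNS = ["year", "estimate", "cv"]

POSTERIOR_COLUMNS = [
    "s_adult", "s_juv", "alpha", "b", "K", "d0", "theta",
    "rmax", "N_start", "N_current",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_catches(path) -> list[ReportedCatch]:
    """Parse a `year,landed,documented,source` CSV into typed records.

    Missing landed counts are empty fields; duplicate years and negative
    counts are rejected with the offending row named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CATCH_COLUMNS, path)
    records = []
    seen: set[int] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            year = int(row.year)
        except ValueError:
            raise ParseError(f"{path} row {i}: non-integer year {row.year!r}") from None
        if year in seen:
            raise ParseError(f"{path} row {i}: duplicate year {year}")
        seen.add(year)
        documented = str(row.documented).strip().lower() in ("true", "1", "yes")
        landed_raw = str(row.landed).strip()
        if documented:
            try:
                landed = float(landed_raw)
            except ValueError:
                raise ParseError(f"{path} row {i}: bad landed count {landed_raw!r}") from None
            if landed < 0:
                raise ParseError(f"{path} row {i}: negative landed count {landed}")
        else:
            if landed_raw not in ("", "nan"):
                raise ParseError(f"{path} row {i}: undocumented year carries landed {landed_raw!r}")
            landed = None
        source = row.source if row.source in SOURCES else None
        if source is None:
            raise ParseError(f"{path} row {i}: unknown source {row.source!r}")
        records.append(ReportedCatch(year=year, landed=landed, documented=documented, source=source))
    return records


def write_catches(records: Sequence[ReportedCatch], path) -> None:
    df = pd.DataFrame(
        {
            "year": [r.year for r in records],
            "landed": [r.landed if r.landed is not None else "" for r in records],
            "documented": [r.documented for r in records],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_surveys(path) -> list[SurveyObservation]:
    """Parse a `year,estimate,cv` CSV; estimate and cv must be positive."""
    df = pd.read_csv(path)
    _require_columns(df, SURVEY_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            year = int(row.year)
            estimate = float(row.estimate)
            cv = float(row.cv)
        except (ValueError, TypeError):
            raise ParseError(f"{path} row {i}: malformed survey row") from None
        if estimate <= 0:
            raise ParseError(f"{path} row {i}: estimate must be > 0, got {estimate}")
        if cv <= 0:
            raise ParseError(f"{path} row {i}: cv must be > 0, got {cv}")
        records.append(SurveyObservation(year=year, estimate=estimate, cv=cv))
    return records


def write_surveys(records: Sequence[SurveyObservation], path) -> None:
    pd.DataFrame(
        {
            "year": [r.year for r in records],
            "estimate": [r.estimate for r in records],
            "cv": [r.cv for r in records],
        }
    ).to_csv(path, index=False)


def read_removals(path) -> RemovalsSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "removals"], path)
    return RemovalsSeries.from_frame(df)


def write_removals(series: RemovalsSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def write_posterior(ensemble: PosteriorEnsemble, path) -> None:
    df = ensemble.draws[POSTERIOR_COLUMNS].copy()
    df["weight"] = ensemble.weights
    df.to_csv(path, index=False)


def read_posterior(path) -> PosteriorEnsemble:
    """Rebuild an ensemble from a posterior CSV; ESS is recomputed from the
    stored weights (the originating seed is not recoverable)."""
    df = pd.read_csv(path)
    _require_columns(df, POSTERIOR_COLUMNS + ["weight"], path)
    weights = df.pop("weight").to_numpy(dtype=float)
    weights = weights / weights.sum()
    ess = float(1.0 / np.sum(weights**2))
    return PosteriorEnsemble(draws=df, weights=weights, ess=ess, seed=None)


@dataclass(frozen=True)
class AssessmentConfig:
    """Everything the full pipeline needs besides the input data files.

    Defaults encode the assessment's standard constants: 5%/30% losses
    ramping over 1960-1970, the printed demographic prior ranges, the ~5000
    carrying-capacity cap, and the 70%-in-5-years increase criterion.
    """

    priors: PriorSpec = field(default_factory=PriorSpec)
    loss: LossSchedule = field(default_factory=LossSchedule)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    projection: ProjectionSpec = field(default_factory=ProjectionSpec)
    seed: int = 42
    start_year: int = 1900
    end_year: int = 2016
    n_draws: int = 50_000
    resample: int = 5_000

    def to_dict(self) -> dict:
        d = {
            "priors": asdict(self.priors),
            "loss": asdict(self.loss),
            "reconstruction": asdict(self.reconstruction),
            "projection": {
                "horizon": self.projection.horizon,
                "criterion": self.projection.criterion,
                "catch_grid": list(self.projection.catch_grid),
                "future_loss_rate": self.projection.future_loss_rate,
            },
            "seed": self.seed,
            "start_year": self.start_year,
            "end_year": self.end_year,
            "n_draws": self.n_draws,
            "resample": self.resample,
        }
        for key in ("s_adult", "s_juv", "alpha", "b", "K", "d0"):
            d["priors"][key] = list(d["priors"][key])
        if isinstance(self.priors.theta, tuple):
            d["priors"]["theta"] = list(self.priors.theta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AssessmentConfig":
        kwargs = {}
        if "priors" in d:
            p = dict(d["priors"])
            for key in ("s_adult", "s_juv", "b", "K", "d0"):
                if key in p:
                    p[key] = tuple(float(x) for x in p[key])
            if "alpha" in p:
                p["alpha"] = tuple(int(x) for x in p["alpha"])
            if isinstance(p.get("theta"), list):
                p["theta"] = tuple(float(x) for x in p["theta"])
            kwargs["priors"] = PriorSpec(**p)
        if "loss" in d:
            kwargs["loss"] = LossSchedule(**d["loss"])
        if "reconstruction" in d:
            r = dict(d["reconstruction"])
            if isinstance(r.get("fill_window"), str) and r["fill_window"] != "all":
                r["fill_window"] = int(r["fill_window"])
            kwargs["reconstruction"] = ReconstructionConfig(**r)
        if "projection" in d:
            pj = dict(d["projection"])
            if "catch_grid" in pj:
                pj["catch_grid"] = tuple(int(c) for c in pj["catch_grid"])
            kwargs["projection"] = ProjectionSpec(**pj)
        for key in ("seed", "start_year", "end_year", "n_draws", "resample"):
            if key in d:
                kwargs[key] = int(d[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AssessmentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Short hash of the canonical config, logged with every run."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
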