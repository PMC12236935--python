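"""Log-linear concentration-response health impact functions.

A relative risk RR reported for a concentration increment (typically
10 ug/m^3) converts to a per-unit-concentration coefficient

    beta = ln(RR) / increment        [per ug/m^3]

and the attributable annual case count in a tract is

    dY = (Y0 / 100 000) * Pop * (1 - exp(-beta * dC))

with Y0 the baseline incidence or prevalence per 100 000 per year, Pop the
tract population and dC the annual-average concentration increment. Y0 is
divided by 100 000 explicitly so the function is dimensionally consistent
with per-100k baseline rates.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exposure import TractExposure

ENDPOINTS = (
    "all_cause_mortality",
    "asthma",
    "diabetes",
    "ischemic_heart_disease",
    "respiratory_tract_cancer",
    "stroke",
    "copd",
)


def rr_to_beta(rr: float, increment: float = 10.0) -> float:
    """Convert a relative risk per ``increment`` ug/m^3 to beta per ug/m^3."""
    if rr <= 0:
        raise ValueError("relative risk must be > 0")
    if increment <= 0:
        raise ValueError("increment must be > 0 ug/m^3")
    return math.log(rr) / increment


def attributable_cases(y0_per_100k: float, population: float, beta: float, delta_c: float) -> float:
    """Annual attributable cases dY = (Y0/1e5) * Pop * (1 - e^(-beta*dC))."""
    if delta_c < 0:
        raise ValueError("delta_c must be >= 0")
    if y0_per_100k < 0 or population < 0:
        raise ValueError("baseline rate and population must be >= 0")
    return (y0_per_100k / 1e5) * population * (1.0 - math.exp(-beta * delta_c))


@dataclass(frozen=True)
class ConcentrationResponse:
    pollutant: str
    endpoint: str
    relative_risk: float
    increment: float = 10.0  # ug/m^3 the RR refers to
    source_label: str = ""

    def __post_init__(self):
        if self.relative_risk <= 0:
            raise ValueError("relative risk must be > 0")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")

    @property
    def beta(self) -> float:
        """beta per ug/m^3, normalized from the source increment at load time."""
        return rr_to_beta(self.relative_risk, self.increment)


@dataclass(frozen=True)
class BaselineRate:
    endpoint: str
    y0_per_100k: float
    year: int = 0
    source_label: str = ""

    def __post_init__(self):
        if self.y0_per_100k < 0:
            raise ValueError("baseline rate must be >= 0")


@dataclass(frozen=True)
class HealthBurden:
    tract_id: str
    pollutant: str
    endpoint: str
    delta_y: float  # attributable cases/yr, fractional allowed
    county: str = ""
    population: int = 0


def burden_table(
    exposures: list[TractExposure],
    crfs: list[ConcentrationResponse],
    rates: list[BaselineRate],
) -> list[HealthBurden]:
    """One burden record per tract × applicable pollutant-endpoint pair.

    Pairs absent from ``crfs`` produce no record (e.g. CO contributes only
    mortality and ischemic heart disease in the default pair map). A CRF
    endpoint without a baseline rate is an error.
    """
    rate_by_endpoint = {r.endpoint: r for r in rates}
    for crf in crfs:
        if crf.endpoint not in rate_by_endpoint:
            raise ValueError(f"missing baseline rate for endpoint {crf.endpoint!r}")
    crfs_by_pollutant: dict[str, list[ConcentrationResponse]] = {}
    for crf in crfs:
        crfs_by_pollutant.setdefault(crf.pollutant, []).append(crf)
    out = []
    for exp in exposures:
        for crf in crfs_by_pollutant.get(exp.pollutant, []):
            y0 = rate_by_endpoint[crf.endpoint].y0_per_100k
            dy = attributable_cases(y0, exp.population, crf.beta, exp.delta_c)
            out.append(
                HealthBurden(exp.tract_id, exp.pollutant, crf.endpoint, dy,
                             county=exp.county, population=exp.population)
            )
    return out


def burdens_to_frame(burdens: list[HealthBurden]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tract_id": [b.tract_id for b in burdens],
            "county": [b.county for b in burdens],
            "pollutant": [b.pollutant for b in burdens],
            "endpoint": [b.endpoint for b in burdens],
            "cases": [b.delta_y for b in burdens],
            "population": [b.population for b in burdens],
        }
    )


def _data_path(name: str):
    return importlib.resources.files("airburden.data") / name


def load_crfs(path: str | Path | None = None) -> list[ConcentrationResponse]:
    """Load concentration-response functions (CSV: pollutant, endpoint, rr, increment_ugm3)."""
    src = path if path is not None else _data_path("crf.csv")
    df = pd.read_csv(src)
    return [
        ConcentrationResponse(
            r.pollutant, r.endpoint, float(r.rr), float(r.increment_ugm3), str(r.source_label)
        )
        for r in df.itertuples()
    ]


def load_baseline_rates(path: str | Path | None = None) -> list[BaselineRate]:
    src = path if path is not None else _data_path("baseline_rates.csv")
    df = pd.read_csv(src)
    return [
        BaselineRate(r.endpoint, float(r.y0_per_100k), int(r.year), str(r.source_label))
        for r in df.itertuples()
    ]
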