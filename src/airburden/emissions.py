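"""Facility emission scenarios.

Annual emission rates for a waste-incineration facility are built either
from throughput (tons of waste burned per year) multiplied by per-pollutant
emission factors (kg emitted per ton burned, AP-42 style), or directly from
reported annual masses. A "controlled" scenario applies control-technology
efficiencies (fractional removal) on top of uncontrolled factors; an
"uncontrolled" scenario assumes no functioning controls. Mean emission
rates in g/s are derived from annual masses over a 365-day year.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

SECONDS_PER_YEAR = 31_536_000  # 365 d × 86 400 s

POLLUTANTS = ("PM", "NOx", "SO2", "CO")


def _data_path(name: str):
    return importlib.resources.files("airburden.data") / name


@dataclass(frozen=True)
class EmissionFactor:
    """Mass emitted per mass of waste burned, in kg per ton."""

    pollutant: str
    factor: float  # kg/ton
    basis: str = "uncontrolled"  # or "controlled"
    source_label: str = ""

    def __post_init__(self):
        if self.factor < 0:
            raise ValueError(f"emission factor for {self.pollutant} must be >= 0")
        if self.basis not in ("uncontrolled", "controlled"):
            raise ValueError(f"unknown factor basis {self.basis!r}")


@dataclass(frozen=True)
class ControlEfficiency:
    """Fractional removal achieved by control equipment (0 = none, 1 = total)."""

    pollutant: str
    efficiency: float
    technology_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(
                f"control efficiency for {self.pollutant} must lie in [0, 1], "
                f"got {self.efficiency}"
            )


@dataclass(frozen=True)
class StackParameters:
    """Physical stack geometry and exhaust conditions."""

    height: float  # m
    diameter: float  # m
    exit_velocity: float  # m/s
    exit_temperature: float  # K

    def __post_init__(self):
        for name in ("height", "diameter", "exit_velocity", "exit_temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"stack {name} must be strictly positive")


@dataclass(frozen=True)
class EmissionScenario:
    """Per-pollutant annual emissions for one facility under one condition.

    ``rates`` maps pollutant name to annual mass in kg/yr; the mean rate in
    g/s follows from the annual mass and is exposed via :meth:`rate_g_s`.
    """

    facility_id: str
    condition: str  # controlled | uncontrolled | reported
    rates: dict[str, float] = field(default_factory=dict)  # kg/yr
    stack: StackParameters | None = None
    throughput: float | None = None  # tons/yr; None for reported scenarios

    def __post_init__(self):
        if self.throughput is not None and self.throughput < 0:
            raise ValueError("throughput must be >= 0")
        for p, m in self.rates.items():
            if m < 0:
                raise ValueError(f"negative annual mass for {p}")

    def rate_g_s(self, pollutant: str) -> float:
        """Mean emission rate in g/s over the year."""
        return self.rates[pollutant] * 1000.0 / SECONDS_PER_YEAR

    @property
    def rates_g_s(self) -> dict[str, float]:
        return {p: self.rate_g_s(p) for p in self.rates}


def scenario_from_throughput(
    throughput: float,
    factors: list[EmissionFactor],
    controls: list[ControlEfficiency] | None = None,
    stack: StackParameters | None = None,
    facility_id: str = "facility",
) -> EmissionScenario:
    """Build a scenario as throughput × factor, optionally × (1 − efficiency).

    Controls only attenuate factors whose basis is "uncontrolled"; a factor
    already expressed on a controlled basis is used as-is.
    """
    if throughput < 0:
        raise ValueError("throughput must be >= 0 tons/year")
    seen: set[str] = set()
    for f in factors:
        if f.pollutant in seen:
            raise ValueError(f"duplicate emission factor for {f.pollutant}")
        seen.add(f.pollutant)
    eff = {c.pollutant: c.efficiency for c in (controls or [])}
    rates = {}
    for f in factors:
        mass = throughput * f.factor
        if f.basis == "uncontrolled" and f.pollutant in eff:
            mass *= 1.0 - eff[f.pollutant]
        rates[f.pollutant] = mass
    condition = "controlled" if controls else "uncontrolled"
    return EmissionScenario(
        facility_id=facility_id,
        condition=condition,
        rates=rates,
        stack=stack,
        throughput=throughput,
    )


def scenario_from_reported(
    annual_masses: dict[str, float],
    stack: StackParameters | None = None,
    facility_id: str = "facility",
) -> EmissionScenario:
    """Build a scenario directly from reported annual masses (kg/yr)."""
    for p, m in annual_masses.items():
        if m < 0:
            raise ValueError(f"reported annual mass for {p} is negative")
    return EmissionScenario(
        facility_id=facility_id,
        condition="reported",
        rates=dict(annual_masses),
        stack=stack,
        throughput=None,
    )


def scale_scenario(scenario: EmissionScenario, new_throughput: float) -> EmissionScenario:
    """Rescale a throughput-based scenario to a new annual throughput.

    Emission rates are homogeneous of degree 1 in throughput, so every rate
    scales by ``new_throughput / old_throughput``.
    """
    if scenario.throughput is None:
        raise ValueError(
            "cannot scale a reported scenario: it has no throughput basis"
        )
    if new_throughput < 0:
        raise ValueError("new throughput must be >= 0")
    if scenario.throughput == 0:
        raise ValueError("cannot scale a zero-throughput scenario")
    k = new_throughput / scenario.throughput
    return replace(
        scenario,
        rates={p: m * k for p, m in scenario.rates.items()},
        throughput=new_throughput,
    )


# ---------------------------------------------------------------------------
# fixture loading and scenario-file round trip


def load_emission_factors(path: str | Path | None = None) -> list[EmissionFactor]:
    """Load emission factors from CSV (pollutant, factor_kg_per_ton, basis, source_label)."""
    src = path if path is not None else _data_path("emission_factors.csv")
    df = pd.read_csv(src)
    return [
        EmissionFactor(r.pollutant, float(r.factor_kg_per_ton), r.basis, str(r.source_label))
        for r in df.itertuples()
    ]


def load_control_efficiencies(path: str | Path | None = None) -> list[ControlEfficiency]:
    src = path if path is not None else _data_path("control_efficiencies.csv")
    df = pd.read_csv(src)
    out = []
    for r in df.itertuples():
        labels = tuple(str(r.technologies).split("|")) if pd.notna(r.technologies) else ()
        out.append(ControlEfficiency(r.pollutant, float(r.efficiency), labels))
    return out


def write_scenario(scenario: EmissionScenario, path: str | Path) -> None:
    """Serialize a scenario to a YAML key-value file."""
    doc: dict = {
        "facility_id": scenario.facility_id,
        "condition": scenario.condition,
        "throughput_tons": scenario.throughput,
        "rates_kg_yr": {p: float(m) for p, m in scenario.rates.items()},
    }
    if scenario.stack is not None:
        doc["stack"] = {
            "height_m": scenario.stack.height,
            "diameter_m": scenario.stack.diameter,
            "exit_velocity_ms": scenario.stack.exit_velocity,
            "exit_temperature_k": scenario.stack.exit_temperature,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_scenario(path: str | Path) -> EmissionScenario:
    doc = yaml.safe_load(Path(path).read_text())
    stack = None
    if "stack" in doc:
        s = doc["stack"]
        stack = StackParameters(
            s["height_m"], s["diameter_m"], s["exit_velocity_ms"], s["exit_temperature_k"]
        )
    return EmissionScenario(
        facility_id=doc["facility_id"],
        condition=doc["condition"],
        rates={p: float(m) for p, m in doc["rates_kg_yr"].items()},
        stack=stack,
        throughput=doc.get("throughput_tons"),
    )
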