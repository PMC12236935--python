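"""Monetization of attributable health burdens.

Mortality cases are valued with the Value of a Statistical Life
($11.74 million, 2025 USD by default); morbidity endpoints use per-case
cost-of-illness values. All unit values are normalized to a common dollar
year with a CPI-style deflator table. The full-precision damage ledger is
kept internally; presentation rounding (1 decimal, $USD millions) is
applied only by report writers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .health import HealthBurden

VSL_2025_USD = 11_740_000.0

LEDGER_COLUMNS = (
    "scenario", "tract_id", "county", "pollutant", "endpoint", "cases", "cost_usd_2025",
)


@dataclass(frozen=True)
class UnitValue:
    endpoint: str
    value_per_case: float  # USD
    dollar_year: int
    kind: str  # VSL | cost_of_illness

    def __post_init__(self):
        if self.value_per_case < 0:
            raise ValueError("value per case must be >= 0")
        if self.kind not in ("VSL", "cost_of_illness"):
            raise ValueError(f"unknown unit-value kind {self.kind!r}")


class DeflatorTable:
    """CPI-style price index by dollar year."""

    def __init__(self, indices: dict[int, float]):
        for y, v in indices.items():
            if v <= 0:
                raise ValueError(f"index for {y} must be > 0")
        self._idx = dict(indices)

    def __contains__(self, year: int) -> bool:
        return year in self._idx

    def index(self, year: int) -> float:
        if year not in self._idx:
            raise KeyError(f"dollar year {year} not in deflator table")
        return self._idx[year]


def inflate(value: float, from_year: int, to_year: int, table: DeflatorTable) -> float:
    """Re-express ``value`` in ``to_year`` dollars: value × index(to)/index(from)."""
    return value * table.index(to_year) / table.index(from_year)


@dataclass
class DamageLedger:
    """Full-precision monetized damages by scenario/tract/county/pollutant/endpoint."""

    records: pd.DataFrame

    def __post_init__(self):
        missing = set(LEDGER_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"ledger missing columns: {sorted(missing)}")

    @property
    def total_cost(self) -> float:
        return float(self.records["cost_usd_2025"].sum())

    @property
    def total_cases(self) -> float:
        return float(self.records["cases"].sum())

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def monetize(
    burdens: list[HealthBurden],
    values: list[UnitValue],
    table: DeflatorTable,
    scenario_label: str = "",
    to_year: int = 2025,
) -> DamageLedger:
    """Value each burden record: cases × per-case value, in ``to_year`` dollars."""
    by_endpoint = {v.endpoint: v for v in values}
    rows = []
    for b in burdens:
        if b.endpoint not in by_endpoint:
            raise ValueError(f"missing unit value for endpoint {b.endpoint!r}")
        uv = by_endpoint[b.endpoint]
        per_case = inflate(uv.value_per_case, uv.dollar_year, to_year, table)
        rows.append(
            (scenario_label, b.tract_id, b.county, b.pollutant, b.endpoint,
             b.delta_y, b.delta_y * per_case)
        )
    return DamageLedger(pd.DataFrame(rows, columns=list(LEDGER_COLUMNS)))


def aggregate(ledger: DamageLedger, by: str) -> pd.DataFrame:
    """Group sums of cases and cost; the grand total is partition-invariant."""
    keys = {"tract": "tract_id", "county": "county", "pollutant": "pollutant",
            "endpoint": "endpoint", "scenario": "scenario"}
    if by not in keys:
        raise ValueError(f"unknown aggregation key {by!r}; choose from {sorted(keys)}")
    if ledger.records.empty:
        raise ValueError("cannot aggregate an empty ledger")
    return (
        ledger.records.groupby(keys[by], as_index=False)[["cases", "cost_usd_2025"]]
        .sum()
        .sort_values(keys[by])
        .reset_index(drop=True)
    )


def scenario_savings(ledger_a: DamageLedger, ledger_b: DamageLedger) -> pd.DataFrame:
    """Per-cell difference cost(a) − cost(b), e.g. uncontrolled − controlled.

    Both ledgers must cover the same tract set and pollutant-endpoint pairs.
    Negative savings are permitted and flagged in the ``negative`` column.
    """
    keys = ["tract_id", "county", "pollutant", "endpoint"]
    a = ledger_a.records.set_index(keys)
    b = ledger_b.records.set_index(keys)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            "mismatched ledger cells; present in one ledger only: "
            f"{sorted(only_a.tolist() + only_b.tolist())[:10]}"
        )
    out = pd.DataFrame(index=a.index)
    out["savings_usd_2025"] = a["cost_usd_2025"] - b["cost_usd_2025"].reindex(a.index)
    out["cases_avoided"] = a["cases"] - b["cases"].reindex(a.index)
    out["negative"] = out["savings_usd_2025"] < 0
    return out.reset_index()


# ---------------------------------------------------------------------------
# fixtures


def _data_path(name: str):
    return importlib.resources.files("airburden.data") / name


def load_unit_values(path: str | Path | None = None) -> list[UnitValue]:
    src = path if path is not None else _data_path("unit_values.csv")
    df = pd.read_csv(src)
    return [
        UnitValue(r.endpoint, float(r.value_per_case_usd), int(r.dollar_year), r.kind)
        for r in df.itertuples()
    ]


def load_deflator(path: str | Path | None = None) -> DeflatorTable:
    src = path if path is not None else _data_path("cpi_deflator.csv")
    df = pd.read_csv(src)
    return DeflatorTable({int(r.year): float(r.index) for r in df.itertuples()})


def load_published_table(which: str) -> pd.DataFrame:
    """Published per-scenario case/cost tables shipped with the package.

    ``which`` is one of "win_waste", "curtis_bay", "combined". Columns:
    year or scenario, pollutant, endpoint, cases, cost_musd (printed values,
    $USD millions at 1 decimal).
    """
    if which not in ("win_waste", "curtis_bay", "combined"):
        raise ValueError(f"unknown table {which!r}")
    return pd.read_csv(_data_path(f"published_{which}.csv"))
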