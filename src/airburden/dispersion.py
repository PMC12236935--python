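"""Steady-state Gaussian plume dispersion surrogate.

Annual-average ground-level concentration increments on a receptor grid are
computed with a textbook Gaussian plume with full ground reflection,
Briggs-interpolation dispersion coefficients (separate urban and rural sets,
keyed to Pasquill–Gifford stability classes A–F) and Briggs buoyancy/momentum
plume rise. This stands in for a regulatory dispersion model: it honours the
same configuration (50 km domain, 2 m flagpole receptors, urban dispersion
option, annual averaging over hourly meteorology) while omitting
boundary-layer scaling, terrain, and building downwash. Externally produced
concentration grids can be ingested instead, so regulatory model output can
drive the downstream exposure and health stages.

The hourly concentration at a receptor at downwind distance x > 0,
crosswind offset y_c and height z, from an effective release height H, is

    C = Q / (2 pi u sigma_y sigma_z)
        * exp(-y_c^2 / (2 sigma_y^2))
        * [exp(-(z - H)^2 / (2 sigma_z^2)) + exp(-(z + H)^2 / (2 sigma_z^2))]

in g/m^3 for Q in g/s, reported in ug/m^3. Hours with wind speed below the
calm threshold are excluded from the average and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emissions import EmissionScenario, StackParameters

CALM_WIND_THRESHOLD = 0.5  # m/s; Gaussian form diverges as u -> 0
G = 9.80665  # m/s^2

STABILITY_CLASSES = ("A", "B", "C", "D", "E", "F")

# Briggs interpolation coefficients: sigma = a * x * (1 + b*x)**p  (x in m).
# Rural = open-country set, urban = McElroy–Pooler-fit set.
_BRIGGS_RURAL = {
    #        sigma_y              sigma_z
    "A": ((0.22, 1e-4, -0.5), (0.20, 0.0, 0.0)),
    "B": ((0.16, 1e-4, -0.5), (0.12, 0.0, 0.0)),
    "C": ((0.11, 1e-4, -0.5), (0.08, 2e-4, -0.5)),
    "D": ((0.08, 1e-4, -0.5), (0.06, 1.5e-3, -0.5)),
    "E": ((0.06, 1e-4, -0.5), (0.03, 3e-4, -1.0)),
    "F": ((0.04, 1e-4, -0.5), (0.016, 3e-4, -1.0)),
}
_BRIGGS_URBAN = {
    "A": ((0.32, 4e-4, -0.5), (0.24, 1e-3, 0.5)),
    "B": ((0.32, 4e-4, -0.5), (0.24, 1e-3, 0.5)),
    "C": ((0.22, 4e-4, -0.5), (0.20, 0.0, 0.0)),
    "D": ((0.16, 4e-4, -0.5), (0.14, 3e-4, -0.5)),
    "E": ((0.11, 4e-4, -0.5), (0.08, 1.5e-4, -0.5)),
    "F": ((0.11, 4e-4, -0.5), (0.08, 1.5e-4, -0.5)),
}


def sigma_y(stability: str, x, urban: bool = False):
    """Briggs horizontal dispersion coefficient (m) at downwind distance x (m)."""
    a, b, p = (_BRIGGS_URBAN if urban else _BRIGGS_RURAL)[stability][0]
    x = np.asarray(x, dtype=float)
    return a * x * (1.0 + b * x) ** p


def sigma_z(stability: str, x, urban: bool = False):
    """Briggs vertical dispersion coefficient (m) at downwind distance x (m)."""
    a, b, p = (_BRIGGS_URBAN if urban else _BRIGGS_RURAL)[stability][1]
    x = np.asarray(x, dtype=float)
    return a * x * (1.0 + b * x) ** p


@dataclass(frozen=True)
class PlumeHour:
    """One hour of dispersion conditions for the plume kernel."""

    wind_speed: float  # m/s
    wind_direction: float  # deg, meteorological (direction wind blows FROM)
    stability_class: str
    ambient_temperature: float = 288.15  # K

    def __post_init__(self):
        if self.stability_class not in STABILITY_CLASSES:
            raise ValueError(f"unknown stability class {self.stability_class!r}")
        if not 0.0 <= self.wind_direction < 360.0:
            raise ValueError("wind direction must lie in [0, 360)")

    @property
    def calm(self) -> bool:
        return self.wind_speed < CALM_WIND_THRESHOLD


def plume_rise(stack: StackParameters, hour: PlumeHour) -> float:
    """Briggs final plume rise (m) above the stack top.

    Buoyancy flux F_b = g v_s d^2 (T_s - T_a) / (4 T_s); final buoyant rise
    uses the neutral/unstable expressions 21.425 F^0.75 / u (F < 55) or
    38.71 F^0.6 / u. When the exhaust is no warmer than ambient the plume
    rise is momentum-only, 3 d v_s / u. The larger of the two applies.
    """
    if stack.exit_temperature <= 0:
        raise ValueError("exit temperature must be positive")
    u = hour.wind_speed
    if u <= 0:
        raise ValueError("plume rise undefined for zero wind speed")
    dT = stack.exit_temperature - hour.ambient_temperature
    rise_m = 3.0 * stack.diameter * stack.exit_velocity / u
    if dT <= 0:
        return rise_m
    fb = G * stack.exit_velocity * stack.diameter**2 * dT / (4.0 * stack.exit_temperature)
    if fb < 55.0:
        rise_b = 21.425 * fb**0.75 / u
    else:
        rise_b = 38.71 * fb**0.6 / u
    return max(rise_b, rise_m)


def plume_concentration(
    q_gs: float,
    hour: PlumeHour,
    x,
    y,
    z,
    effective_height: float,
    urban: bool = False,
):
    """Hourly Gaussian plume concentration (ug/m^3) at receptors (x, y, z).

    Coordinates are source-centred planar meters; x east, y north. Receptors
    at non-positive downwind distance receive zero. Vectorised over receptor
    arrays.
    """
    if hour.calm:
        raise ValueError("calm hour: Gaussian plume undefined below the calm threshold")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if q_gs == 0.0:
        return np.zeros(np.broadcast(x, y, z).shape)
    # unit vector pointing downwind (met convention: wind FROM wind_direction)
    theta = math.radians((hour.wind_direction + 180.0) % 360.0)
    ux, uy = math.sin(theta), math.cos(theta)
    xd = x * ux + y * uy  # downwind distance
    yc = -x * uy + y * ux  # crosswind offset
    out = np.zeros(xd.shape)
    mask = xd > 0.0
    if not np.any(mask):
        return out
    sy = sigma_y(hour.stability_class, xd[mask], urban)
    sz = sigma_z(hour.stability_class, xd[mask], urban)
    u = hour.wind_speed
    h = effective_height
    zz = np.broadcast_to(z, xd.shape)[mask]
    c = (
        q_gs
        / (2.0 * np.pi * u * sy * sz)
        * np.exp(-(yc[mask] ** 2) / (2.0 * sy**2))
        * (
            np.exp(-((zz - h) ** 2) / (2.0 * sz**2))
            + np.exp(-((zz + h) ** 2) / (2.0 * sz**2))
        )
    )
    out[mask] = c * 1e6  # g/m^3 -> ug/m^3
    return out


@dataclass(frozen=True)
class ReceptorGrid:
    """Receptor locations in source-centred planar meters.

    The default layout is polar: rings of receptors at 36 compass directions
    out to the domain radius, at a fixed flagpole (breathing-zone) height.
    """

    x: np.ndarray
    y: np.ndarray
    elevation: np.ndarray
    flagpole_height: float = 2.0
    domain_radius: float = 50_000.0

    def __post_init__(self):
        if self.flagpole_height < 0:
            raise ValueError("flagpole height must be >= 0")
        r = np.hypot(self.x, self.y)
        if np.any(r > self.domain_radius * (1 + 1e-9)):
            raise ValueError("receptor outside domain radius")

    def __len__(self) -> int:
        return self.x.size

    @property
    def z(self) -> np.ndarray:
        return self.elevation + self.flagpole_height

    @classmethod
    def polar(
        cls,
        n_directions: int = 36,
        n_rings: int = 40,
        domain_radius: float = 50_000.0,
        flagpole_height: float = 2.0,
    ) -> "ReceptorGrid":
        """Polar grid: geometric radial spacing resolves near-field gradients."""
        # geometric rings from 100 m out to the domain edge
        radii = np.geomspace(100.0, domain_radius, n_rings)
        angles = np.arange(n_directions) * (2.0 * np.pi / n_directions)
        rr, aa = np.meshgrid(radii, angles)
        x = (rr * np.sin(aa)).ravel()
        y = (rr * np.cos(aa)).ravel()
        return cls(
            x=x,
            y=y,
            elevation=np.zeros(x.size),
            flagpole_height=flagpole_height,
            domain_radius=domain_radius,
        )


@dataclass
class ConcentrationField:
    """Annual-average concentration increment (ug/m^3) at each receptor."""

    pollutant: str
    grid: ReceptorGrid
    values: np.ndarray
    scenario_label: str = ""
    provenance: str = "internal_plume"  # or "ingested_grid"
    calm_hours_skipped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.grid):
            raise ValueError("one value per receptor required")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def domain_maximum(self) -> float:
        """Domain-wide maximum annual average — the headline summary diagnostic."""
        return float(self.values.max())

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"x_m": self.grid.x, "y_m": self.grid.y, "concentration_ugm3": self.values}
        ).to_csv(path, index=False)


def annual_average_field(
    scenario: EmissionScenario,
    met,
    grid: ReceptorGrid,
    urban_population: int = 0,
    source_xy: tuple[float, float] = (0.0, 0.0),
    scenario_label: str = "",
) -> dict[str, ConcentrationField]:
    """Annual-average field per pollutant: mean plume over non-calm hours.

    A positive ``urban_population`` (e.g. 565 000 for a Baltimore-scale urban
    core) switches the dispersion coefficients to the urban set. The plume
    kernel depends on the pollutant only through the emission rate, so a
    unit-rate field is accumulated once and scaled per pollutant.
    ``met`` is any iterable of hourly records with wind_speed, wind_direction,
    stability_class, ambient_temperature and calm attributes.
    """
    if scenario.stack is None:
        raise ValueError("scenario must carry stack parameters for dispersion")
    urban = urban_population > 0
    hours = list(met.records if hasattr(met, "records") else met)
    active = [h for h in hours if not getattr(h, "calm", False)]
    n_calm = len(hours) - len(active)
    if not active:
        raise ValueError("all meteorological hours are calm; no plume can be computed")
    sx, sy_ = source_xy
    rx, ry = grid.x - sx, grid.y - sy_
    acc = np.zeros(len(grid))
    for h in active:
        ph = PlumeHour(h.wind_speed, h.wind_direction, h.stability_class,
                       getattr(h, "ambient_temperature", 288.15))
        heff = scenario.stack.height + plume_rise(scenario.stack, ph)
        acc += plume_concentration(1.0, ph, rx, ry, grid.z, heff, urban=urban)
    unit_field = acc / len(active)
    fields = {}
    for pollutant in scenario.rates:
        fields[pollutant] = ConcentrationField(
            pollutant=pollutant,
            grid=grid,
            values=unit_field * scenario.rate_g_s(pollutant),
            scenario_label=scenario_label or scenario.condition,
            provenance="internal_plume",
            calm_hours_skipped=n_calm,
        )
    return fields


def superpose(fields: list[ConcentrationField]) -> ConcentrationField:
    """Sum concentration fields from multiple facilities on a shared grid."""
    if not fields:
        raise ValueError("nothing to superpose")
    first = fields[0]
    for f in fields[1:]:
        if f.pollutant != first.pollutant or len(f.grid) != len(first.grid):
            raise ValueError("superposition requires a shared pollutant and grid")
    return ConcentrationField(
        pollutant=first.pollutant,
        grid=first.grid,
        values=np.sum([f.values for f in fields], axis=0),
        scenario_label=first.scenario_label,
        provenance=first.provenance,
        calm_hours_skipped=max(f.calm_hours_skipped for f in fields),
    )


def ingest_concentration_grid(
    path: str | Path,
    pollutant: str,
    flagpole_height: float = 2.0,
    domain_radius: float | None = None,
    scenario_label: str = "",
) -> ConcentrationField:
    """Read an externally produced x,y,concentration grid (CSV).

    Expected columns: x_m, y_m, concentration_ugm3. Malformed rows raise
    with their line number; negative concentrations are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty concentration grid file") from None
    required = {"x_m", "y_m", "concentration_ugm3"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: malformed value in column {col} at line {line}")
    if df.empty:
        raise ValueError(f"{path}: concentration grid has no rows")
    vals = df["concentration_ugm3"].astype(float).to_numpy()
    if np.any(vals < 0):
        raise ValueError(f"{path}: negative concentration values are not allowed")
    x = df["x_m"].astype(float).to_numpy()
    y = df["y_m"].astype(float).to_numpy()
    radius = domain_radius if domain_radius is not None else float(np.hypot(x, y).max())
    grid = ReceptorGrid(
        x=x, y=y, elevation=np.zeros(x.size),
        flagpole_height=flagpole_height, domain_radius=max(radius, 1.0),
    )
    return ConcentrationField(
        pollutant=pollutant, grid=grid, values=vals,
        scenario_label=scenario_label, provenance="ingested_grid",
    )
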