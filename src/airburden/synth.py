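"""Synthetic study-area, covariate, and meteorology generators.

Every pipeline input that would normally come from census boundaries,
surface meteorology archives, or social-vulnerability tables can be
generated here so the full chain is testable without external downloads.

Tracts are a perturbed Voronoi tessellation of random centroids clipped to
a circular modeling domain — irregular contiguous polygons resembling
census tracts. Coordinates are planar meters centred on the emission
source. Populations are log-normal (median ≈ 3 000, typical of census
tracts). Social-vulnerability covariates are 16 percentage-scaled variables
mirroring the four SVI themes, with a latent mortality-rate signal built
from planted linear coefficients so regression stages can be validated by
parameter recovery. Hourly meteorology has a von Mises wind-direction
distribution about a prevailing direction, Weibull wind speeds, and
Pasquill stability classes drawn from a fixed distribution weighted toward
neutral (class D).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon, mapping, shape

SVI_COVARIATE_NAMES = (
    # theme 1: socioeconomic status
    "below_poverty",
    "unemployed",
    "housing_cost_burden",
    "no_high_school_diploma",
    "no_health_insurance",
    # theme 2: household characteristics
    "age_65_plus",
    "age_17_minus",
    "disability",
    "single_parent",
    "limited_english",
    # theme 3: racial & ethnic minority status
    "minority",
    # theme 4: housing type & transportation
    "multi_unit_housing",
    "mobile_homes",
    "crowding",
    "no_vehicle",
    "group_quarters",
)


@dataclass(frozen=True)
class Tract:
    tract_id: str
    polygon: Polygon
    population: int
    county: str

    def __post_init__(self):
        if self.population < 0:
            raise ValueError(f"tract {self.tract_id}: population must be >= 0")
        if not self.polygon.is_valid:
            raise ValueError(f"tract {self.tract_id}: invalid (self-intersecting?) polygon")


@dataclass(frozen=True)
class SyntheticStudyArea:
    """Tract geometries with populations, in source-centred planar meters."""

    tracts: tuple[Tract, ...]
    source_location: tuple[float, float] = (0.0, 0.0)
    domain_radius: float = 50_000.0

    def __post_init__(self):
        ids = [t.tract_id for t in self.tracts]
        if len(set(ids)) != len(ids):
            raise ValueError("tract ids must be unique")
        sx, sy = self.source_location
        for t in self.tracts:
            c = t.polygon.centroid
            if math.hypot(c.x - sx, c.y - sy) > self.domain_radius * (1 + 1e-9):
                raise ValueError(f"tract {t.tract_id} centroid outside domain radius")

    def __len__(self) -> int:
        return len(self.tracts)

    @property
    def total_population(self) -> int:
        return sum(t.population for t in self.tracts)


@dataclass(frozen=True)
class SyntheticCovariateSpec:
    """Planted linear effects of vulnerability covariates on mortality rate."""

    covariate_names: tuple[str, ...] = SVI_COVARIATE_NAMES
    planted_coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 50.0  # baseline attributable-mortality rate per 100k
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.planted_coefficients) - set(self.covariate_names)
        if unknown:
            raise ValueError(f"unknown coefficient names: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MetHour:
    wind_speed: float  # m/s
    wind_direction: float  # deg [0, 360)
    stability_class: str
    ambient_temperature: float  # K
    calm: bool = False

    def __post_init__(self):
        if not self.calm and self.wind_speed <= 0:
            raise ValueError("wind speed must be > 0 unless the calm flag is set")
        if not 0.0 <= self.wind_direction < 360.0:
            raise ValueError("wind direction must lie in [0, 360)")


@dataclass(frozen=True)
class SyntheticMeteorology:
    records: tuple[MetHour, ...]

    def __len__(self) -> int:
        return len(self.records)


# D-weighted stability climatology (mid-latitude surrogate)
_STABILITY_PROBS = dict(zip("ABCDEF", (0.05, 0.10, 0.15, 0.40, 0.15, 0.15)))


def generate_study_area(
    n_tracts: int, domain_radius: float, seed: int
) -> SyntheticStudyArea:
    """Perturbed-Voronoi tessellation of ``n_tracts`` tracts inside the domain.

    Deterministic for a fixed seed. Centroids are drawn uniformly over the
    disc (with one forced near the source so some tract always contains it),
    jittered, and their Voronoi cells clipped to the domain circle. County
    labels partition tracts by compass sector of their centroid.
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    if domain_radius <= 0:
        raise ValueError("domain_radius must be > 0")
    rng = np.random.default_rng(seed)
    disc = Point(0.0, 0.0).buffer(domain_radius, quad_segs=64)

    if n_tracts == 1:
        polys = [disc]
    else:
        # uniform-on-disc centroids; first point pulled toward the source
        r = domain_radius * np.sqrt(rng.uniform(0, 1, n_tracts))
        a = rng.uniform(0, 2 * np.pi, n_tracts)
        pts = np.column_stack([r * np.sin(a), r * np.cos(a)])
        pts[0] *= 0.05
        pts += rng.normal(0, 0.01 * domain_radius, pts.shape)  # perturbation
        # ghost ring makes every interior Voronoi cell finite
        ring_a = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        ghosts = 4.0 * domain_radius * np.column_stack([np.sin(ring_a), np.cos(ring_a)])
        vor = Voronoi(np.vstack([pts, ghosts]))
        polys = []
        for i in range(n_tracts):
            region = vor.regions[vor.point_region[i]]
            cell = Polygon(vor.vertices[region])
            polys.append(cell.intersection(disc))

    n_counties = max(1, min(4, n_tracts // 6 + 1))
    tracts = []
    for i, poly in enumerate(polys):
        if poly.is_empty or poly.area <= 0:
            raise RuntimeError("degenerate Voronoi cell; try another seed")
        if poly.geom_type == "MultiPolygon":  # keep the dominant piece
            poly = max(poly.geoms, key=lambda g: g.area)
        pop = int(round(float(rng.lognormal(mean=math.log(3000.0), sigma=0.6))))
        c = poly.centroid
        sector = int(((math.degrees(math.atan2(c.x, c.y)) % 360.0) / 360.0) * n_counties)
        tracts.append(
            Tract(
                tract_id=f"24510{i:06d}",
                polygon=poly,
                population=pop,
                county=f"County{min(sector, n_counties - 1):02d}",
            )
        )
    return SyntheticStudyArea(
        tracts=tuple(tracts), source_location=(0.0, 0.0), domain_radius=domain_radius
    )


def generate_covariates(
    area: SyntheticStudyArea, spec: SyntheticCovariateSpec
) -> pd.DataFrame:
    """Tract × covariate table with a latent mortality-rate signal.

    Covariates are percentage-like in [0, 100]. The latent rate is
    ``intercept + Σ coefficient×covariate + N(0, noise_sd)`` — the ground
    truth the disparities regression should recover.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(area)
    cov = rng.uniform(0.0, 100.0, size=(n, len(spec.covariate_names)))
    df = pd.DataFrame(cov, columns=list(spec.covariate_names))
    df.insert(0, "tract_id", [t.tract_id for t in area.tracts])
    rate = np.full(n, spec.intercept, dtype=float)
    for name, coef in spec.planted_coefficients.items():
        rate += coef * df[name].to_numpy()
    if spec.noise_sd > 0:
        rate += rng.normal(0.0, spec.noise_sd, n)
    df["latent_mortality_rate_per_100k"] = rate
    return df


def generate_meteorology(
    n_hours: int,
    prevailing_direction: float = 270.0,
    seed: int = 0,
    calm_fraction: float = 0.02,
) -> SyntheticMeteorology:
    """Hourly meteorology with a prevailing wind direction.

    Directions are von Mises about the prevailing direction (circular mean
    equals it in expectation); speeds are Weibull(k=2, λ=4 m/s); a small
    fraction of hours are flagged calm; temperatures follow a smooth annual
    cycle about 288 K.
    """
    if n_hours < 1:
        raise ValueError("n_hours must be >= 1")
    rng = np.random.default_rng(seed)
    dirs = np.degrees(rng.vonmises(math.radians(prevailing_direction), 1.5, n_hours)) % 360.0
    speeds = 4.0 * rng.weibull(2.0, n_hours)
    calm = rng.uniform(0, 1, n_hours) < calm_fraction
    speeds = np.where(calm, 0.2, np.maximum(speeds, 0.6))
    classes = rng.choice(
        list(_STABILITY_PROBS), p=list(_STABILITY_PROBS.values()), size=n_hours
    )
    t = np.arange(n_hours)
    temps = 288.15 + 10.0 * np.sin(2 * np.pi * t / 8760.0) + rng.normal(0, 1.5, n_hours)
    records = tuple(
        MetHour(
            wind_speed=float(speeds[i]),
            wind_direction=float(dirs[i]),
            stability_class=str(classes[i]),
            ambient_temperature=float(temps[i]),
            calm=bool(calm[i]),
        )
        for i in range(n_hours)
    )
    return SyntheticMeteorology(records=records)


# ---------------------------------------------------------------------------
# round-trip I/O


def write_study_area_geojson(area: SyntheticStudyArea, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(t.polygon),
            "properties": {"id": t.tract_id, "population": t.population, "county": t.county},
        }
        for t in area.tracts
    ]
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "source_location": list(area.source_location),
        "domain_radius_m": area.domain_radius,
    }
    Path(path).write_text(json.dumps(doc))


def read_study_area_geojson(path: str | Path) -> SyntheticStudyArea:
    doc = json.loads(Path(path).read_text())
    tracts = tuple(
        Tract(
            tract_id=f["properties"]["id"],
            polygon=shape(f["geometry"]),
            population=int(f["properties"]["population"]),
            county=f["properties"]["county"],
        )
        for f in doc["features"]
    )
    return SyntheticStudyArea(
        tracts=tracts,
        source_location=tuple(doc.get("source_location", (0.0, 0.0))),
        domain_radius=float(doc.get("domain_radius_m", 50_000.0)),
    )


def write_meteorology_csv(met: SyntheticMeteorology, path: str | Path) -> None:
    pd.DataFrame(
        {
            # %.17g preserves float64 exactly, so the CSV round-trips bitwise
            "wind_speed_ms": [h.wind_speed for h in met.records],
            "wind_direction_deg": [h.wind_direction for h in met.records],
            "stability_class": [h.stability_class for h in met.records],
            "ambient_temperature_k": [h.ambient_temperature for h in met.records],
            "calm": [int(h.calm) for h in met.records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_meteorology_csv(path: str | Path) -> SyntheticMeteorology:
    df = pd.read_csv(path, float_precision="round_trip")
    return SyntheticMeteorology(
        records=tuple(
            MetHour(
                wind_speed=float(r.wind_speed_ms),
                wind_direction=float(r.wind_direction_deg),
                stability_class=str(r.stability_class),
                ambient_temperature=float(r.ambient_temperature_k),
                calm=bool(r.calm),
            )
            for r in df.itertuples()
        )
    )
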