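"""End-to-end orchestration: one config file in, all stage outputs out.

A run generates (or loads) the study area, meteorology and covariates,
builds each named emission scenario, disperses it to annual-average
concentration fields (superposing facilities additively at the field level,
since the health impact function is nonlinear in concentration), assigns
tract exposures, computes burdens, monetizes them, differences designated
scenario pairs into savings tables, and fits the disparities regressions.
A manifest records the seed, config hash, package version and output
hashes so fixed-seed runs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .disparities import screen_and_fit
from .dispersion import ReceptorGrid, annual_average_field, superpose
from .emissions import (
    StackParameters,
    load_control_efficiencies,
    load_emission_factors,
    scenario_from_throughput,
)
from .exposure import assign_exposures, exposures_to_frame
from .health import burden_table, burdens_to_frame, load_baseline_rates, load_crfs
from .synth import (
    SyntheticCovariateSpec,
    generate_covariates,
    generate_meteorology,
    generate_study_area,
    write_meteorology_csv,
    write_study_area_geojson,
)
from .valuation import load_deflator, load_unit_values, monetize, scenario_savings

log = logging.getLogger("airburden")


@dataclass
class RunConfig:
    seed: int = 0
    domain_radius_m: float = 50_000.0
    urban_population: int = 565_000
    n_tracts: int = 25
    met_hours: int = 240
    prevailing_direction_deg: float = 270.0
    covariate_noise_sd: float = 5.0
    planted_coefficients: dict = field(default_factory=dict)
    grid_directions: int = 36
    grid_rings: int = 40
    flagpole_m: float = 2.0
    exposure_assignment: str = "per_receptor"
    facilities: list = field(default_factory=list)
    scenarios: list = field(default_factory=list)
    savings_pairs: list = field(default_factory=list)
    disparity_scenarios: list = field(default_factory=list)
    fixtures: dict = field(default_factory=dict)  # optional CSV path overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        cfg = cls(
            seed=int(doc.get("seed", 0)),
            domain_radius_m=float(doc.get("domain_radius_m", 50_000.0)),
            urban_population=int(doc.get("urban_population", 565_000)),
            n_tracts=int(doc.get("study_area", {}).get("n_tracts", 25)),
            met_hours=int(doc.get("meteorology", {}).get("n_hours", 240)),
            prevailing_direction_deg=float(
                doc.get("meteorology", {}).get("prevailing_direction_deg", 270.0)
            ),
            covariate_noise_sd=float(doc.get("covariates", {}).get("noise_sd", 5.0)),
            planted_coefficients=dict(
                doc.get("covariates", {}).get("planted_coefficients", {})
            ),
            grid_directions=int(doc.get("grid", {}).get("n_directions", 36)),
            grid_rings=int(doc.get("grid", {}).get("n_rings", 40)),
            flagpole_m=float(doc.get("grid", {}).get("flagpole_m", 2.0)),
            exposure_assignment=doc.get("exposure_assignment", "per_receptor"),
            facilities=doc.get("facilities", []),
            scenarios=doc.get("scenarios", []),
            savings_pairs=[tuple(p) for p in doc.get("savings_pairs", [])],
            disparity_scenarios=list(doc.get("disparity_scenarios", [])),
            fixtures=dict(doc.get("fixtures", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        labels = [s["label"] for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise ValueError("scenario labels must be unique")
        fac_ids = {f["id"] for f in self.facilities}
        for s in self.scenarios:
            for fs in s["facilities"]:
                if fs["id"] not in fac_ids:
                    raise ValueError(f"scenario {s['label']!r} references unknown facility {fs['id']!r}")
        for a, b in self.savings_pairs:
            if a not in labels or b not in labels:
                raise ValueError(f"savings pair ({a}, {b}) references unknown scenario")
        for p in self.fixtures.values():
            if not Path(p).exists():
                raise ValueError(f"fixture path does not exist: {p}")


def _stack_from(doc: dict) -> StackParameters:
    return StackParameters(
        height=float(doc["height_m"]),
        diameter=float(doc["diameter_m"]),
        exit_velocity=float(doc["exit_velocity_ms"]),
        exit_temperature=float(doc["exit_temperature_k"]),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, output_dir: str | Path) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    t0 = time.perf_counter()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    factors = load_emission_factors(config.fixtures.get("emission_factors"))
    controls = load_control_efficiencies(config.fixtures.get("control_efficiencies"))
    crfs = load_crfs(config.fixtures.get("crf"))
    rates = load_baseline_rates(config.fixtures.get("baseline_rates"))
    unit_values = load_unit_values(config.fixtures.get("unit_values"))
    deflator = load_deflator(config.fixtures.get("cpi_deflator"))

    area = generate_study_area(config.n_tracts, config.domain_radius_m, config.seed)
    met = generate_meteorology(
        config.met_hours, config.prevailing_direction_deg, seed=config.seed + 1
    )
    cov_spec = SyntheticCovariateSpec(
        planted_coefficients=config.planted_coefficients,
        noise_sd=config.covariate_noise_sd,
        seed=config.seed + 2,
    )
    covariates = generate_covariates(area, cov_spec)
    grid = ReceptorGrid.polar(
        config.grid_directions, config.grid_rings, config.domain_radius_m, config.flagpole_m
    )
    write_study_area_geojson(area, out / "tracts.geojson")
    write_meteorology_csv(met, out / "meteorology.csv")
    covariates.to_csv(out / "covariates.csv", index=False)
    log.info("synth: %d tracts, %d met hours, %d receptors",
             len(area), len(met), len(grid))

    facilities = {f["id"]: f for f in config.facilities}
    ledgers = {}
    burdens_by_scenario = {}
    exposures_by_scenario = {}
    for sdoc in config.scenarios:
        label = sdoc["label"]
        ts = time.perf_counter()
        fields_by_pollutant: dict[str, list] = {}
        for fs in sdoc["facilities"]:
            fac = facilities[fs["id"]]
            stack = _stack_from(fac["stack"])
            ctl = controls if fs.get("condition", "uncontrolled") == "controlled" else None
            scen = scenario_from_throughput(
                float(fs["throughput_tons"]), factors, ctl, stack, facility_id=fs["id"]
            )
            fields = annual_average_field(
                scen, met, grid,
                urban_population=config.urban_population,
                source_xy=tuple(fac.get("location_m", (0.0, 0.0))),
                scenario_label=label,
            )
            for p, f in fields.items():
                fields_by_pollutant.setdefault(p, []).append(f)
        exposures = []
        for p, flist in fields_by_pollutant.items():
            fld = superpose(flist) if len(flist) > 1 else flist[0]
            fld.write_csv(out / f"concentration_{label}_{p}.csv")
            if fld.calm_hours_skipped:
                log.warning("%s/%s: %d calm hours excluded", label, p, fld.calm_hours_skipped)
            exposures.extend(assign_exposures(fld, area, config.exposure_assignment))
        n_nearest = sum(1 for e in exposures if e.assignment_method == "nearest_point")
        if n_nearest:
            log.warning("%s: %d tract-pollutant cells used nearest-point fallback",
                        label, n_nearest)
        exposures_to_frame(exposures).to_csv(out / f"exposure_{label}.csv", index=False)
        burdens = burden_table(exposures, crfs, rates)
        burdens_to_frame(burdens).to_csv(out / f"burden_{label}.csv", index=False)
        ledger = monetize(burdens, unit_values, deflator, scenario_label=label)
        ledger.write_csv(out / f"damages_{label}.csv")
        ledgers[label] = ledger
        burdens_by_scenario[label] = burdens
        exposures_by_scenario[label] = exposures
        log.info("scenario %s: %d burden records, total $%.0f (%.2fs)",
                 label, len(burdens), ledger.total_cost, time.perf_counter() - ts)

    for a, b in config.savings_pairs:
        sav = scenario_savings(ledgers[a], ledgers[b])
        sav.to_csv(out / f"savings_{a}_minus_{b}.csv", index=False)
        log.info("savings %s - %s: total $%.0f", a, b, sav["savings_usd_2025"].sum())

    for label in config.disparity_scenarios:
        df = _disparity_inputs(burdens_by_scenario[label], exposures_by_scenario[label],
                               covariates)
        results = screen_and_fit(df, scenario=label)
        results.to_csv(out / f"disparities_{label}.csv", index=False)
        log.info("disparities %s: %d result rows", label, len(results))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_tracts": config.n_tracts,
        "met_hours": config.met_hours,
        "scenarios": sorted(ledgers),
        "total_cost_usd_2025": {k: v.total_cost for k, v in sorted(ledgers.items())},
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*")) if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete in %.2fs", time.perf_counter() - t0)
    return manifest


def _disparity_inputs(burdens, exposures, covariates: pd.DataFrame) -> pd.DataFrame:
    """Merge mortality rate, summed concentration, and covariates per tract."""
    bdf = burdens_to_frame(burdens)
    mort = (
        bdf[bdf["endpoint"] == "all_cause_mortality"]
        .groupby("tract_id", as_index=False)
        .agg(cases=("cases", "sum"), population=("population", "first"))
    )
    mort["mortality_rate_per_100k"] = (
        mort["cases"] / mort["population"].clip(lower=1) * 1e5
    )
    edf = exposures_to_frame(exposures)
    dc = edf.groupby("tract_id", as_index=False)["delta_c_ugm3"].sum().rename(
        columns={"delta_c_ugm3": "delta_c"}
    )
    return mort.merge(dc, on="tract_id").merge(covariates, on="tract_id")


def load_demo_config() -> RunConfig:
    """The shipped demo: 25 tracts, 240 met hours, four scenarios."""
    import importlib.resources

    with importlib.resources.as_file(
        importlib.resources.files("airburden.data") / "demo_config.yaml"
    ) as p:
        return RunConfig.from_yaml(p)
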