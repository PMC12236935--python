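# airburden

Health-damage assessment for point-source air pollution — built around the
case of municipal and medical waste incinerators. `airburden` turns annual
facility emissions into monetized, tract-level health damages and quantifies
how those damages fall across socially vulnerable communities:

1. **Emissions** — annual per-pollutant rates (PM, NOx, SO₂, CO) from waste
   throughput × AP-42-style emission factors, under *controlled* (pollution
   control equipment operating) and *uncontrolled* bounds, or from reported
   annual masses.
2. **Dispersion** — annual-average ground-level concentration increments ΔC
   (μg/m³) on a 50 km receptor grid from a steady-state Gaussian plume with
   Briggs urban/rural dispersion coefficients and Briggs plume rise, at 2 m
   breathing-zone receptors. Grids produced by a regulatory dispersion model
   can be ingested instead.
3. **Exposure** — tract ΔC is the mean of receptors inside the tract, or the
   value at the receptor nearest the tract centroid when none falls inside.
4. **Health impact** — relative risks convert to coefficients β = ln(RR)/Δc,
   and attributable annual cases per tract follow the log-linear impact
   function

   ΔY = (Y₀ / 100 000) · Pop · (1 − e^(−β·ΔC))

   with Y₀ the baseline incidence/prevalence per 100 000.
5. **Valuation** — mortality at the Value of a Statistical Life
   ($11.74 million, 2025 USD), morbidity at per-case cost of illness, all
   CPI-normalized to 2025 dollars; scenario differencing yields the damages
   avoidable by enforcing pollution controls.
6. **Disparities** — tract attributable-mortality rate regressed on 16
   social-vulnerability covariates (univariate Gaussian GLMs, p < 0.05
   screen, then a joint model adjusted for concentration and population).

A synthetic-data module generates census-tract-like geometries (perturbed
Voronoi tessellations), log-normal populations, hourly meteorology, and
vulnerability covariates with planted linear effects, so the entire chain
runs and is testable without any external data.

## Worked example

Run the shipped demo (25 synthetic tracts, 240 hours of meteorology, one
medical-waste incinerator under four throughput/control scenarios):

```bash
airburden run --config src/airburden/data/demo_config.yaml --out out_demo
```

which prints:

```
max_controlled: total damages $190,940 (2025 USD)
max_uncontrolled: total damages $1,366,730 (2025 USD)
typical_controlled: total damages $88,655 (2025 USD)
typical_uncontrolled: total damages $634,824 (2025 USD)
```

Reading: burning 26 000 t/yr with controls operating causes ≈ $0.09 M/yr in
damages across the synthetic 25-tract area; with controls failed the same
throughput causes ≈ $0.63 M/yr, so enforcing controls would avoid ≈ $0.55 M/yr;
at the 56 000 t/yr maximum permitted throughput the uncontrolled damages
scale to ≈ $1.37 M/yr. (These magnitudes reflect the synthetic study area's
~77 000 residents; a metropolitan population is hundreds of times larger.)
The output directory also contains per-scenario concentration grids,
tract-exposure and burden tables, damage ledgers, per-tract savings tables,
disparities regression results, and a manifest with input hashes — reruns
with the same seed are byte-identical.

Library use mirrors the stages:

```python
import airburden as ab

stack = ab.StackParameters(height=30, diameter=1.2, exit_velocity=15, exit_temperature=450)
scen = ab.scenario_from_throughput(26_000, ab.emissions.load_emission_factors(),
                                   ab.emissions.load_control_efficiencies(), stack)
met = ab.generate_meteorology(8760, prevailing_direction=270, seed=1)
grid = ab.ReceptorGrid.polar()                      # 36 directions x 40 rings to 50 km
fields = ab.annual_average_field(scen, met, grid, urban_population=565_000)
area = ab.generate_study_area(100, 50_000, seed=1)
exposures = ab.assign_exposures(fields["PM"], area)
```

## Scope notes

Shipped emission factors, relative risks, baseline rates, and morbidity unit
values are editable synthetic stand-ins of realistic magnitude (see
`src/airburden/data/`); the Gaussian plume is a documented surrogate for a
full regulatory dispersion model (no terrain, building downwash, or
boundary-layer scaling), whose output can be ingested via
`ingest_concentration_grid`. See `docs/methods.md` for models, parameters,
and limitations.
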