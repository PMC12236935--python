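# Methods

## Emission scenarios

Annual emissions are linear in waste throughput: mass(p) = T × EF(p), with T
in tons/yr and EF(p) in kg emitted per ton burned, following the AP-42
convention for waste incinerators. A *controlled* scenario multiplies each
uncontrolled-basis factor by (1 − η(p)), where η is the fractional removal
of the facility's control train (dry sorbent injection, activated carbon
injection, fabric filtration). Defaults shipped with the package: η = 0.984
(PM), 0.50 (NOx), 0.67 (SO₂), 0 (CO) — values consistent with fabric-filter
dominance for particles, retrofit-level NOx reduction, and sorbent-injection
SO₂ capture. Factors marked `basis: controlled` are used as-is. Mean rates
in g/s divide the annual mass by 31 536 000 s (365-day year); no temporal
emission profile is applied, since all downstream quantities are annual
averages. Reported-emissions scenarios bypass the throughput model and
cannot be rescaled (there is no throughput basis to scale).

## Dispersion surrogate

Ground-level concentration increments come from the steady-state Gaussian
plume with full ground reflection:

C(x, y_c, z) = Q/(2π u σ_y σ_z) · exp(−y_c²/2σ_y²) ·
[exp(−(z−H)²/2σ_z²) + exp(−(z+H)²/2σ_z²)]

with downwind distance x > 0, crosswind offset y_c, receptor height z
(default 2 m flagpole, flat terrain), and effective height H = stack height
+ Briggs plume rise. Buoyancy flux F_b = g·v_s·d²·(T_s−T_a)/(4T_s); final
rise is 21.425·F_b^0.75/u for F_b < 55 m⁴/s³, else 38.71·F_b^0.6/u, floored
by the momentum rise 3·d·v_s/u (momentum-only when the exhaust is at or
below ambient temperature). σ_y and σ_z use the Briggs interpolation
formulas a·x·(1+b·x)^p keyed to Pasquill–Gifford classes A–F, with separate
rural (open-country) and urban (McElroy–Pooler-fit) coefficient sets; a
positive urban-population setting (the configured default, 565 000,
representing a Baltimore-scale urban core) selects the urban set.

This is deliberately a surrogate, not a re-implementation, of a regulatory
model: boundary-layer scaling, terrain, land-cover-derived surface
parameters and building downwash are all omitted. Grids computed externally
can be ingested (`ingest_concentration_grid`, CSV columns x_m, y_m,
concentration_ugm3) and drive all downstream stages unchanged.

Annual averaging: hours with wind speed below 0.5 m/s are excluded (the
kernel diverges as u → 0) and counted; the per-receptor field is the mean
over the remaining hours. The per-receptor field drives exposure; the
domain-wide maximum is exposed only as a summary diagnostic
(`ConcentrationField.domain_maximum`). An alternative, deliberately
conservative exposure mode assigning every tract the domain maximum is
available behind `assignment="domain_max"` but is not the default, since it
would inflate damages by orders of magnitude.

The default receptor layout is polar — 36 directions × 40 rings,
geometrically spaced from 100 m to the 50 km domain edge — because
concentration gradients are steepest within ~1 km of the stack.

## Exposure assignment

Tracts containing at least one receptor get the arithmetic mean of the
contained receptor values (`within_average`); tracts with none get the value
at the receptor nearest the tract centroid (`nearest_point`, ties broken by
lowest receptor index); tracts whose centroid lies outside the domain get
ΔC = 0 and are flagged `outside_domain`. Containment uses the closed
boundary (a receptor exactly on a shared edge counts for each adjacent
tract); with random tessellations against a polar grid this is a
measure-zero event and keeps the rule deterministic without an orientation
convention. Population-weighted sub-tract averaging is out of scope.

## Health impact function

β = ln(RR)/Δc normalizes each relative risk to a per-μg/m³ coefficient at
load time (sources state RR per varying increments, most commonly
10 μg/m³). Attributable cases are ΔY = (Y₀/10⁵)·Pop·(1−e^(−β·ΔC)); the
explicit /10⁵ keeps the function dimensionally consistent with per-100 000
baseline rates. For β·ΔC < 10⁻³ this agrees with the first-order expansion
(Y₀/10⁵)·Pop·β·ΔC to within 0.1 %, which is the regime the annual-average
increments occupy away from the immediate near field. Per-pollutant burdens
are computed independently and summed — no interaction or subadditivity
across pollutants. The default pollutant–endpoint map is PM → {mortality,
asthma, diabetes, ischemic heart disease, respiratory tract cancer,
stroke}; NOx → {mortality, asthma, IHD}; SO₂ → {mortality, IHD}; CO →
{mortality, IHD}. COPD has a shipped baseline rate but no default pair;
adding a CRF row activates it. Annual-average ΔC is used directly as the
long-term exposure change; no cessation lag.

## Valuation

Mortality is valued at the Value of a Statistical Life, $11.74 M in 2025
dollars; morbidity at per-case cost-of-illness values. A CPI-style deflator
table (annual index, 2014–2025 vintage) normalizes unit values stated in
other dollar years. The ledger keeps full precision; 1-decimal
$USD-million rounding is presentation-only. Scenario savings difference two
ledgers cell-by-cell over the shared (tract, pollutant, endpoint) index;
negative cells are permitted and flagged, and with controlled emissions
pointwise below uncontrolled ones all cells are non-negative. County totals
come from the tract's county label, not from geometry.

The published facility tables shipped under `data/published_*.csv` carry
printed 3-decimal case counts and 1-decimal cost cells. Because the case
counts are themselves rounded, a cost cell whose exact product lies within
11.74 × 0.0005 ≈ $0.006 M of a rounding boundary can print either neighbor;
the regression check accepts exactly that ambiguity and nothing more.

## Disparities regression

The outcome is the tract's attributable all-cause-mortality rate per
100 000 (mortality ΔY summed over pollutants ÷ population × 10⁵). Stage 1
fits one Gaussian-family GLM (identity link — ordinary least squares) per
covariate, 16 covariates on the 0–100 percentage scale mirroring the four
social-vulnerability themes; constant covariates are skipped with a
warning. Stage 2 refits the covariates passing a raw p < 0.05 screen — no
multiple-testing correction, matching common practice for this design — in
one joint Gaussian GLM additionally adjusted for the tract's total
concentration increment (summed over pollutants; per-pollutant adjustment
is a caller choice via `adjusters`) and population. Wald 95 % intervals
throughout; perfect collinearity is detected by rank and reported with the
offending columns.

## Synthetic data

The generator emulates the *structure* of the real inputs, not their
values: Voronoi tracts (irregular, contiguous, tiling a 50 km disc;
planar meters centred on the source, so no geodesy); log-normal populations
with median ≈ 3 000; uniform-percentage covariates with a latent mortality
rate that is exactly linear in the planted coefficients plus Gaussian
noise; von Mises wind directions about a prevailing direction, Weibull
(k = 2, λ = 4 m/s) speeds, ~2 % calm hours, stability classes drawn from a
fixed distribution weighted toward neutral D (0.05/0.10/0.15/0.40/0.15/0.15
for A–F), and a smooth annual temperature cycle. What passing tests show:
the arithmetic, geometry and statistics of every stage are correct, and
planted regression structure is recovered at nominal coverage. What they do
not show: agreement with any real facility's damages — real meteorology is
autocorrelated, real tract populations correlate with vulnerability, and
real emission factors differ from the shipped stand-ins.

## Numerical and design choices

- Calm threshold 0.5 m/s; excluded hours are counted on the field object.
- Receptor containment and centroids via planar shapely geometry.
- Fixed seeds everywhere; generators take independent derived seeds
  (seed, seed+1, seed+2) for area, meteorology and covariates so stages can
  be regenerated independently.
- Meteorology CSVs are written at %.17g and read with round-trip float
  parsing, so file round trips are bitwise exact; fixed-seed pipeline runs
  are byte-identical.
- Demo problem sizes (25 tracts, 240 met hours, 36 × 40 receptors, four
  scenarios) were chosen so a full run completes in about a second while
  every stage — including multi-scenario differencing and both disparities
  fits — is exercised end to end; statistical checks use 200-tract areas
  and 500 replicates, enough for coverage estimates with ±2 % binomial
  error.

## Known limitations

- No NOx → ozone / secondary PM chemistry, deposition, or short-term
  (hourly design value) statistics; the plume is annual-average only.
- Emission factors and health constants are stand-ins; results scale
  linearly (factors, VSL) or log-linearly (RRs) in them.
- The disparities model ignores spatial autocorrelation; standard errors on
  real, spatially clustered damages would be optimistic.
- Ingestion-pathway exposure (soil/water/food) and greenhouse-gas damages
  are out of scope.
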