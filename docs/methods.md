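# Methods

## Soil NOx flux model

The simulator computes an hourly soil NO flux per grid cell as the product
of an emission-factor term and three environmental modulations:

```
flux = [A_biome + γ · N_avail] · f(T) · g(θ) · P(l_dry) · (1 − CRF)
```

**Emission factor.** The biome dependence of soil NO release is represented
as an affine function of available nitrogen: a per-biome base flux
`A_biome` (ng N m⁻² s⁻¹) plus a slope γ (ng N m⁻² s⁻¹ per kg N ha⁻¹) times
`N_avail`. The affine form is a modelling choice — the underlying
parameterization literature tabulates biome factors rather than a
functional form — and both the base table and γ are configuration. A
constant per-biome canopy-reduction fraction CRF (default 0) stands in for
a full canopy-uptake scheme, which is out of scope.

**Temperature.** `f(T) = exp(0.103 T)` with T the top-layer soil
temperature in °C. The response is defined on 0–30 °C; outside that
interval T is clamped, which keeps f continuous and bounded
(1 ≤ f ≤ e^3.09) without asserting behaviour where the form is not
specified.

**Moisture.** `g(θ) = a θ exp(−b θ²)` over water-filled pore space
θ ∈ [0, 1]. The coefficients are not free: `b = 1/(2 θ_opt²)` places the
maximum at θ_opt (0.2 for arid soils, 0.3 elsewhere, following laboratory
and field evidence), and `a = e^{1/2}/θ_opt` normalizes `g(θ_opt) = 1`.
Only the maximizer is constrained by the source literature; the unit
normalization is this package's convention, chosen so that f·g·P purely
modulates the emission factor. Users who need a different absolute scale
fold it into `A_biome` and γ.

**Pulsing.** Rewetting of long-dry soil reactivates water-stressed
bacteria and produces a transient emission burst. At a wetting event
(θ crossing the dry threshold from below after `l_dry` dry hours) the pulse
amplitude is `13.01 ln(l_dry) − 53.6`; a pulse starts only if that bracket
exceeds 1 (for `l_dry ≤ 61 h` it does not), decays as `exp(−c t)` with t
the hours since wetting, and ends when the enhancement first reaches 1. The
factor is floored at 1 — a wetting after a short dry spell must not
*suppress* emissions. Two constants here are deliberate package choices,
exposed in `BdsnpParams` because no published value pins them down:

- `pulse_c = 0.068 h⁻¹` (≈ 14.7 h e-folding), the pulse rise/fall rate;
- `dry_theta_threshold = 0.15` WFPS, the definition of a "dry" hour.

**Nitrogen pools.** `N_avail = n_natural + n_fert + n_dep` (kg N ha⁻¹).
The natural pool is constant. The fertilizer pool obeys first-order decay
with e-folding time τ_fert (default 120 days) and is fed by a daily
application schedule; annual fertilizer is spread uniformly across the
growing-season window since the within-season shape is not constrained by
the inputs this package models. Deposition nitrogen is an exogenous
constant pool — in a full chemistry-transport model it would be coupled to
simulated deposition, which is out of scope. Emissions do not deplete the
pools (no mass feedback); pool decay is the only sink.

**Units.** Fluxes are ng N m⁻² s⁻¹; mass totals are Tg N via exact unit
algebra (flux × cell area × 3600 s per hour / 10²¹ ng per Tg), with cell
areas supplied explicitly since synthetic grids carry no geodesy.

## Exposure metrics

MDA8 is the maximum over the 17 within-calendar-day 8-hour running means
(window start hours 00–16 local); a window is valid with ≥ 6 of 8 hours
present and a day with ≥ 1 valid window. NDGT70 counts valid days with
MDA8 strictly above 70 ppb. AOT40 accumulates `max(0, O3 − 40 ppb)` over
daytime hours, defined as 08:00–19:59 local. The completeness rules and the
daytime window follow common TOAR-style practice and are configurable; all
metrics operate in local time. Network concentrations reported in µg m⁻³ at
273.15 K and 1 atm convert to ppb by the factor 22.414/48.00 (ideal-gas
molar volume over the O3 molar mass). Quality control beyond completeness
is deliberately minimal and documented as package policy: negative values
and runs of ≥ 24 identical consecutive values (stuck instrument) are
dropped.

The H2O2/HNO3 ratio diagnoses the photochemical regime: above a threshold
(default 1, regionally variable) ozone formation leans NOx-sensitive,
otherwise NOx-saturated/transitional. Ozone production efficiency is the
molar ratio of ozone produced to NOx emitted (masses divided by 48 g mol⁻¹
and 14 g mol⁻¹ N respectively).

## Scenario attribution and the soil penalty

Source contributions are zero-out differences between labeled scenario
fields; the soil–anthropogenic interaction is the second difference
`(BASE − NoAnthro) − (NoSoil − NoAnthroSoil)`. Response curves express the
percent decrease of a regional metric against the anthropogenic reduction
fraction r ∈ [0, 1]; regional aggregation is an (optionally area-weighted)
simple mean over a region mask or site list.

Curves are summarised by a two-parameter logarithmic fit. Two named forms
are provided, both anchored through the origin and invertible in closed
form:

- `Δ = p ln(1 + q r)` — concave (diminishing returns);
- `Δ = −p ln(1 − q r)`, 0 < q < 1 — convex (accelerating returns). This is
  the exact percent-change shape produced when ozone depends
  logarithmically on total NOx emission, as in the synthetic surface: under
  NOx-saturated chemistry, cuts become more effective as emissions fall.

The default fitter tries both and keeps the smaller residual; the form is
also selectable, and a custom `(form, inverse)` pair can be plugged in.
Parameter boxes are finite so the near-linear ridge (p → ∞, q → 0 with p·q
fixed) terminates instead of stalling the optimizer; fits on that ridge are
flagged `near_linear` since only the product p·q is then identified.
Bootstrap intervals use residual resampling with the n/(n−2) degrees-of-
freedom inflation.

The required reduction for a target percent decrease inverts the fitted
form; targets beyond the r = 1 response return a flagged "unreachable"
result rather than an extrapolation. The soil NOx penalty is
`required(with soil) − required(without soil)` in percentage points, and a
factor-of-2 soil-emission uncertainty is propagated by repeating any
scale-dependent computation at 0.5× and 2× and reporting the min–max
envelope around the central estimate.

## Synthetic data

The generators exist so every stage can be tested against known ground
truth; they do not mimic any real meteorological archive or inventory.

- **Meteorology**: diurnal-sine soil temperature (mean 17 °C, half-range
  16 °C plus small cell offsets, so the record spans the full 0–30 °C
  response domain) and bucket-model soil moisture
  `θ(t+Δt) = θ(t) e^{−Δt/τ} + rain pulse` with τ = 72 h and per-cell daily
  rain draws. One cell is scripted to stay rain-free until its dry spell
  exceeds the configured target and is then wetted, so every record long
  enough to hold it exercises the pulse machinery.
- **Fertilizer**: uniform daily application over the growing-season window
  summing to 60 kg N ha⁻¹ a⁻¹ per fertilized cell (a typical intensive-
  cropland order of magnitude), with 30% of cells unfertilized to exercise
  fertilizer-fraction separation.
- **Scenario ozone**: `O3(t) = d(t) · (B0 + α ln(1 + κ(E_anthro + E_soil)))`
  with diurnal weight d(t) (half-sine 07:00–19:00 local over a 0.3
  nocturnal floor — chosen so MDA8 windows are nontrivial), defaults
  B0 = 20 ppb, α = 25 ppb, κ = 1.2, E_anthro = 3, E_soil = 1 (arbitrary
  emission units), Gaussian noise of configurable sd clipped at 0 ppb
  (clipping slightly biases low values, which recovery tolerances must
  absorb when noise is large). The saturating (logarithmic) dependence on
  total emission is the essential feature: it makes soil emissions suppress
  the anthropogenic ozone response, giving a nonzero interaction and
  penalty with a closed form the tests check against. HNO3 rises linearly
  with total emission while H2O2 is constant, so the regime ratio falls
  with anthropogenic emissions. Ground-truth parameters are stored with the
  dataset (NetCDF attribute and JSON sidecar) and tests read them rather
  than re-deriving.
- **Station series**: the diurnal shape scaled to a 75 ppb daytime peak
  with 4 ppb noise, reported in µg m⁻³ at standard conditions with a
  configurable missing-hour fraction, alongside the exact ppb truth.

What passing tests show, and do not show: they verify the implemented
formulas, state machines, metric definitions and fitting/inversion algebra
exactly or to stated tolerances on data whose generating process is known.
They do not validate the parameterization against field fluxes, nor the
synthetic emission–ozone surface against chemistry-transport output — the
surface has the right qualitative curvature but makes no quantitative claim
about any real region.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded from the
  config; identical config + seed is bit-identical everywhere.
- Problem sizes used in the shipped tests and examples (grids of order
  5×8 cells, records of 8–30 days, 50 fit replicates with 200 bootstrap
  resamples) were chosen as the smallest sizes that exercise every code
  path and leave the statistical checks well-powered.
- The short simulation window starts the fertilizer pool from zero; without
  a spin-up the fertilizer-induced emission share is below its steady-state
  value (pool e-folding is 120 days). Component attribution is still exact
  because component runs share meteorology and pulse state.
- Gridded I/O is NetCDF3 (xarray scipy engine) with CF-style dimensions
  `time/lat/lon` and mandatory `units` attributes; schema violations raise
  named errors rather than warnings.
- The modelling surface follows the statsmodels convention where a model is
  genuinely fitted to data: `LogResponseModel` (data + form) produces a
  `LogResponseFit` (params, standard errors, diagnostics, `summary()`,
  inversion). The emission simulator is mechanistic, not fitted, so it is a
  driver object (`BdsnpModel.run() → EmissionField`) rather than a
  model/results pair.

## Known limitations

- No process chemistry: nitrification/denitrification, HONO and N2O
  co-emission, and canopy exchange beyond a constant factor are absent.
- The deposition pool is exogenous; there is no coupling to simulated
  deposition.
- Emission does not deplete the nitrogen pools.
- The H2O2/HNO3 generator is monotone by construction; it supports testing
  the indicator's plumbing, not regime thresholds for any real airshed.
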