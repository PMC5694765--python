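# Methods

This note documents the models implemented in `agscc`, the defaults and
units of their parameters, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## Yield response surface

The estimation sample is a meta-database of published point estimates of
crop yield change under perturbed climate. Each record carries the crop
(maize, rice, wheat, soybean), a country, the local growing-season
temperature change ΔT (°C), the study's scenario and reference CO₂
concentrations (ppm), the precipitation change ΔP (percent), a flag for
on-farm agronomic adaptation, and the country-crop baseline growing-season
temperature T̄ (°C), attached from an input table (multi-country studies
are assigned upstream to the country with the highest production of the
crop). Records with missing ΔP are imputed as zero with a logged count —
many process-based studies hold rainfall fixed, and dropping them would
silently change the sample.

The model is a 21-coefficient no-intercept OLS regression: per-crop ΔT,
ΔT², ΔT·T̄ and ΔT²·T̄ terms (16 coefficients), the two CO₂ amplitudes, the
precipitation slope, and the adaptation interaction and intercept. Because
there is no constant, the no-adaptation response is forced through the
origin, and R² is the uncentered version (1 − SSR/Σy²), the quantity
maximized when selecting the CO₂ half-saturation constants.

**CO₂ fertilization.** f(ΔCO₂) = ΔCO₂/(ΔCO₂ + A), concave and saturating
at 1, with A a free half-saturation constant chosen by grid search on fit
R² — separately for C3 crops (default 100 ppm) and the C4 crop, maize
(default 50 ppm); ties go to the smaller constant. All study CO₂
perturbations are re-expressed against a 360 ppm modern reference:
ΔCO₂ = max(S − 360, 0), where S is the scenario concentration, regardless
of the study's own baseline. The one-sided clamp reflects that the
fertilization curve is undefined in sign below the reference and the sample
is forward-looking. A caveat learned from the synthetic experiments: with
realistic noise the C4 constant is only weakly identified, because the
amplitude β₆ can largely compensate for a mis-set A over the sampled ΔCO₂
range; the constants should be regarded as calibrated, not precisely
estimated.

**Adaptation adjustment.** Studies that include adaptation receive an
intercept β₉ (management changes that would raise yields in today's climate
too) and an interaction β₈ΔT (true climate adaptation). All predictions are
"adjusted": the value at the query minus the value at zero climate change
with the same adaptation flag, which nets out β₉, retains β₈ΔT, and makes
d(0) = 0 exactly. Predicted losses are floored at −99% at prediction time
only — never during estimation.

**Uncertainty.** A block bootstrap resamples whole studies (equal
probability, with replacement, the same number of blocks as observed) and
refits; blocking at the model level is available via `block_key="model_id"`
for the robustness check that multiple studies may share a model. The
default is 1500 replicates with 750 as a light preset; desk-scale analyses
here use 250. Intervals are empirical type-7 (linear-interpolation)
quantiles of the draws, and only confidence intervals are produced — the
relevant uncertainty is in the expected response. A rank-deficient resample
is redrawn from the advancing generator stream (cap 10 per replicate), so
replicate counts are exact and runs are bit-reproducible under a seed.
Because the design matrix does not depend on the resample, it is built once
and rows are re-indexed per replicate; 250 replicates on a ~1000-record
database take well under a second.

**Specification variants.** Four robustness specifications are available:
restriction to publications from 2005 on, crop-specific cubic ΔT terms,
interaction of the temperature terms with a process-vs-empirical dummy, and
replacement of the single adaptation dummy with cultivar / planting-date /
both dummies (each with its ΔT interaction). These return a flexible fit
object with standard errors and t-statistics (via statsmodels) since their
column sets differ from the base model's 21.

## Gridded yield shocks

Grids are regular lat-lon `xarray` fields, cell-center coordinates, area
weights ∝ cos(latitude), NaN as the missing mask; inputs must be aligned
(no internal regridding). The pattern field is (future − base)/global
warming per cell, treated purely as a spatial shape. CO₂ at a warming level
comes from a least-squares quadratic fitted to (global ΔT, ppm) pairs from
a scenario run (diagnostics: adjusted R² and dof = n − 3). Baseline
growing-season temperature is computed per country and crop — monthly
temperatures averaged over the planting-to-harvest window (inclusive,
wrapping December to January), then production-weighted over the country's
cells; zero-production country-crops are missing, never zero. Cells whose
country lacks a baseline are masked.

The per-cell shock composes the pieces: local ΔT = pattern × global ΔT,
CO₂ from the quadratic re-based against 360 ppm, ΔP = 0 (no precipitation
scenario is defined), adaptation on by default, the −99% floor applying.
Two conventions deserve note. First, the response-surface ΔT is interpreted
as change from the modern baseline while the quadratic's argument is
warming on the scenario's own base period; because the fitted quadratic
evaluates below 360 ppm at zero warming and the re-basing clamps at zero,
the zero-warming field is identically zero without special-casing — both
conventions are recorded in the output attributes. Second, CO₂ fertilization
is applied to all crops by default; a `c4_co2=False` flag excludes maize
only, since published analyses differ on this choice. Warming levels beyond
3 °C warn (the damage calibration range); beyond 6 °C error.

Ensemble utilities (for gridded crop-model archives): the first year an
annual global-temperature series reaches a warming level, with a centered
11-year window for averaging co-indexed fields (a truncated window is an
error, not a silent shrink; an optional centered running mean can smooth the
series before detection); per-cell choice of irrigated results where
irrigated area strictly exceeds rainfed area (ties to rainfed); and the
simple unweighted mean over crop-model × GCM members.

## Damage functions

Welfare tables carry, per region and warming level (1/2/3 °C), the
productivity, terms-of-trade, and allocative-efficiency components and the
total equivalent variation, plus the value of production of the four crops
as normalizer. The additive decomposition is validated to 1 × 10⁻⁶ relative
tolerance (with a unit absolute floor for near-zero totals) before any
fitting; country-level tables aggregate to regions by summation (components
and normalizers alike), which conserves the global total and is order
invariant.

Each region's damage function maps global mean warming to welfare as a
fraction of crop production value, with d(0) = 0. The piecewise-linear
method interpolates the knots (0, 1, 2, 3 °C) exactly and extrapolates
beyond 3 °C with the 2→3 °C slope, so it is continuous everywhere. The
quadratic method fits a·ΔT + b·ΔT² by least squares through (0,0) and the
three points; the origin constraint is imposed by omitting the intercept,
since a free intercept would violate d(0) = 0 — an unconstrained variant is
available behind `through_origin=False` because the constraint is a
modeling choice, not a mathematical necessity. Bootstrap uncertainty enters
from upstream: the 2.5th/97.5th-quantile coefficient surfaces produce low
and high welfare tables, and this module simply builds three damage
functions per region; it does not itself resample.

## Climate module and the SCC

The climate core uses DICE-2013R central parameters: a linear three-box
carbon cycle (atmosphere 588, upper ocean/biosphere 1350, deep ocean
10000 GtC at preindustrial equilibrium; five-year transfer fractions
b₁₂ = 0.088, b₂₃ = 0.0025 with reciprocal transfers set by the equilibrium
masses), logarithmic forcing F = 3.8·log₂(C/C_pre) W m⁻², equilibrium
climate sensitivity 2.9 °C, and a two-layer temperature update (five-year
speeds c₁ = 0.098, c₄ = 0.025, exchange c₃ = 0.088). The published
five-year step is annualized by linear interpolation of the transition
matrices, M₁ = I + (M₅ − I)/5, which leaves every equilibrium unchanged:
preindustrial is an exact fixed point, carbon mass is conserved to machine
precision, and sustained doubled CO₂ converges to the configured climate
sensitivity. Atmospheric GtC converts to ppm at 2.13 GtC/ppm; emissions
enter in GtCO₂ (×12/44 to GtC). Exogenous non-CO₂ forcing is a property of
the scenario, not of the climate parameters, so the bare module has a clean
zero-emissions fixed point; the bundled BAU carries the conventional 0.25 →
0.70 W m⁻² linear ramp to 2100.

Damages are additive over 16 world regions × 2 sectors: agriculture
(damage-function value × agricultural output value, i.e. ag share × GDP)
and a configurable lumped "other sectors" function on full GDP; positive
values are welfare losses. The SCC adds a 1 GtCO₂ pulse to the reference
emissions path in 2020, differences the damage streams, discounts at a
constant annual rate (3% default; 2.5% and 5% presets) back to the pulse
year, and divides by the pulse mass in tons. The horizon defaults to 2300.
Because everything is additive, the (region, sector) contributions sum to
the total to floating-point precision, a halved pulse changes the per-ton
value by well under 1%, and swapping the agricultural functions leaves all
other contributions bitwise unchanged — the experiment that isolates the
effect of updated agricultural science on the SCC. Currency is treated as
scenario-consistent real dollars; Ramsey discounting, equity weighting, and
parameter Monte Carlo are out of scope.

## Synthetic data: what it does and does not show

The generators produce inputs with the *statistical structure* the pipeline
assumes, not emulations of the real datasets.

- **Meta-database**: 56 studies with 10–25 points each (~10³ records), crop
  mix in proportion 344/238/336/92, one country per study with fixed
  (country, crop) baseline temperatures in 10–28 °C, ΔT ∈ [0, 6] °C,
  scenario CO₂ ∈ [360, 750] ppm (30% of studies hold CO₂ fixed),
  ΔP ∈ [−20, 20]%, adaptation probability 0.45 with cultivar/planting-date/
  both types. Yields are the true surface plus a Gaussian study random
  effect and idiosyncratic noise giving within-study equicorrelation
  ρ = 0.3 at total sd 10 percentage points. The true surface is calibrated
  to a realistic qualitative shape — losses steepen with warming and with
  hot baselines, and the fertilization amplitudes give +11.5% (C3) and
  +8.7% (C4) at doubled-preindustrial CO₂. The generator's job is to
  exercise the estimator and the block bootstrap; it says nothing about
  publication bias, non-Gaussian study effects, or real covariate
  correlation structure.
- **Grids**: an 18 × 36 lat-lon lattice with a polar-amplified pattern
  field normalized to an exact area-weighted mean of one, baseline
  temperature declining with |latitude|, seasonal cycles that flip phase
  across the equator, production concentrated in a few mid-latitude
  hotspots, contiguous block countries, and southern-hemisphere calendars
  shifted six months. No ocean mask, soils, or real geography.
- **Welfare tables**: the three components are drawn with the total imposed
  as their sum, magnitudes growing with warming, dominant negative
  productivity effects, terms-of-trade varying in sign across regions. The
  economics is drawn, not solved — no CGE mechanism is emulated.
- **BAU scenario**: a deterministic logistic emissions ramp (peak
  140 GtCO₂/yr, midpoint 2042, timescale 30 yr, declining after 2150),
  frozen in the packaged config after a one-time calibration so the default
  climate module reaches 4.0 °C above preindustrial in 2100 from the
  2010-era initial state; regional GDP/population shares and constant
  agricultural output shares (1–8% of GDP) are drawn once per seed.
  The warming calibration is independent of the seed.

Consequently, green tests demonstrate that the estimator is unbiased and
its bootstrap approximately calibrated *under these conditions*, that the
spatial, damage, and SCC algebra is exact, and that the chain composes —
not that any particular real-world dollar figure is reproduced. Reproducing
published SCC values additionally requires the real deposited inputs
(meta-database, CGE welfare tables, scenario paths and the legacy damage
module's central parameters), which the CSV/JSON interfaces accept
unchanged.

## Problem sizes and seeds

Desk-scale defaults keep every stage fast: 250-replicate bootstraps for
interval construction (0.1 s at ~1000 records), 200 outer replications for
the bias/coverage experiment (~25 s), an 18 × 36 grid, and a 2010–2300
annual climate horizon (~0.3 ms per run). All randomness flows through
`numpy.random.default_rng` seeds derived from a single `SeedSequence`, so
every artifact in the repository is exactly reproducible from the seed
printed beside it.

## Known limitations

- The response surface extrapolates a single global functional form;
  spatial heterogeneity beyond baseline temperature (soils, irrigation,
  nutrient stress) is deliberately smoothed out.
- The C4 half-saturation constant is weakly identified at realistic noise
  (see above).
- The welfare step consumes CGE output; it cannot generate economics, and
  the synthetic tables' terms-of-trade structure is stochastic, not
  equilibrium-derived.
- The climate module is CO₂-plus-exogenous-forcing only; non-CO₂ gas
  cycles are not modeled.
- The "other sectors" damage function is a single lump per region; no
  within-sector dynamics (rate effects, adaptation over time) are
  represented.
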