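"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis -- meta-database, gridded climate and production
layers, CGE-style welfare tables, and a business-as-usual socio-economic
scenario -- can be generated here so the full chain runs and is testable
without any download.  The generators emulate structure, not the real data:
the meta-database is drawn from a known response surface with study-level
clustering (so the block bootstrap has something real to capture), the
pattern field has polar amplification and an area-weighted mean of one, the
welfare tables impose the three-component additive decomposition, and the
BAU scenario is calibrated so the default climate module reaches about
4 degC above preindustrial in 2100.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import load_config
from .damage import DamageFunction, WelfareTable
from .response_surface import (
    COEF_LABELS,
    CROPS,
    CoefficientSet,
    MetaDatabase,
)
from .scc import Scenario
from .spatial import CropCalendar, area_weights

#: The 16 aggregate world regions used for damage functions and the SCC.
FUND_REGIONS = (
    "USA", "CAN", "WEU", "JPK", "ANZ", "EEU", "FSU", "MDE",
    "CAM", "SAM", "SAS", "SEA", "CHI", "NAF", "SSA", "SIS",
)


def paperlike_coefficients() -> CoefficientSet:
    """Synthetic 'true' response surface with realistic qualitative shape.

    Losses steepen with warming, warming hurts more where the baseline
    growing season is already hot (negative temperature-baseline
    interactions), and the fertilization amplitudes are set so a doubling of
    CO2 from preindustrial levels (adjusted dCO2 = 200 ppm) raises yields by
    11.5% for C3 crops and 8.7% for the C4 crop.  Synthetic throughout --
    these are generator inputs, not estimates.
    """
    beta = {
        "dT:maize": 0.6, "dT2:maize": -0.28, "dT_tbar:maize": -0.09, "dT2_tbar:maize": -0.006,
        "dT:rice": 0.9, "dT2:rice": -0.22, "dT_tbar:rice": -0.07, "dT2_tbar:rice": -0.004,
        "dT:wheat": 1.1, "dT2:wheat": -0.30, "dT_tbar:wheat": -0.11, "dT2_tbar:wheat": -0.005,
        "dT:soybean": 1.3, "dT2:soybean": -0.35, "dT_tbar:soybean": -0.12, "dT2_tbar:soybean": -0.007,
        "fco2_c3": 17.25,  # 17.25 * f1(200 ppm; A=100) = 11.5%
        "fco2_c4": 10.875,  # 10.875 * f2(200 ppm; A=50) = 8.7%
        "dP": 0.05,
        "dT_adapt": 0.2,
        "adapt": 5.0,
    }
    return CoefficientSet(
        values=np.array([beta[lab] for lab in COEF_LABELS]),
        a_c3=100.0,
        a_c4=50.0,
    )


@dataclass
class MetaGenSpec:
    """Generator settings for a synthetic point-estimate meta-database.

    Defaults mirror the shape of the real estimation sample: 56 studies with
    10-25 point estimates each (order 10^3 records), crop mix weighted like
    the published counts (344 maize / 238 rice / 336 wheat / 92 soybean),
    within-study equicorrelation rho = 0.3, residual sd 10 percentage
    points, temperature perturbations up to 6 degC and scenario CO2 up to
    750 ppm.
    """

    truth: CoefficientSet = field(default_factory=paperlike_coefficients)
    n_studies: int = 56
    points_per_study: tuple[int, int] = (10, 25)
    rho: float = 0.3
    sd: float = 10.0
    delta_T_range: tuple[float, float] = (0.0, 6.0)
    co2_range: tuple[float, float] = (360.0, 750.0)
    co2_fixed_prob: float = 0.3  # studies that hold CO2 at the modern level
    precip_range: tuple[float, float] = (-20.0, 20.0)
    adapt_prob: float = 0.45
    crop_weights: dict = field(
        default_factory=lambda: {"maize": 344, "rice": 238, "wheat": 336, "soybean": 92}
    )
    n_countries: int = 20
    baseline_T_range: tuple[float, float] = (10.0, 28.0)
    n_models: int = 28
    empirical_prob: float = 8 / 56
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.sd <= 0:
            raise ValueError("residual sd must be positive")
        lo, hi = self.points_per_study
        if hi < lo or lo < 1:
            raise ValueError("points_per_study range is degenerate")


def gen_meta_database(spec: MetaGenSpec) -> MetaDatabase:
    """Draw a synthetic meta-database from a known response surface.

    Yield changes are the regression mean at sampled covariates plus a
    Gaussian study random effect and idiosyncratic noise, giving
    equicorrelation ``rho`` within study.  Baseline growing-season
    temperatures are fixed per (country, crop), as in the real attachment
    procedure.
    """
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth
    crops = list(spec.crop_weights)
    p_crop = np.array([spec.crop_weights[c] for c in crops], dtype=float)
    p_crop /= p_crop.sum()
    tbar_table = {
        (k, c): rng.uniform(*spec.baseline_T_range)
        for k in range(spec.n_countries)
        for c in crops
    }
    rows = []
    for s in range(spec.n_studies):
        study = f"S{s:03d}"
        country = int(rng.integers(spec.n_countries))
        method = "empirical" if rng.random() < spec.empirical_prob else "process"
        pub_year = int(rng.integers(1997, 2013))
        model = f"M{int(rng.integers(spec.n_models)):02d}"
        co2_fixed = rng.random() < spec.co2_fixed_prob
        n_pts = int(rng.integers(spec.points_per_study[0], spec.points_per_study[1] + 1))
        u_study = rng.normal(0.0, spec.sd * np.sqrt(spec.rho))
        for _ in range(n_pts):
            crop = crops[rng.choice(len(crops), p=p_crop)]
            dT = rng.uniform(*spec.delta_T_range)
            co2 = 360.0 if co2_fixed else rng.uniform(*spec.co2_range)
            dP = rng.uniform(*spec.precip_range)
            adapt = bool(rng.random() < spec.adapt_prob)
            if adapt:
                atype = rng.choice(["cultivar", "planting_date", "both"], p=[0.2, 0.15, 0.65])
            else:
                atype = "none"
            tbar = tbar_table[(country, crop)]
            mean = truth.predict_raw(crop, dT, tbar, co2, dP, adapt)
            dy = mean + u_study + rng.normal(0.0, spec.sd * np.sqrt(1.0 - spec.rho))
            rows.append(
                {
                    "study_id": study,
                    "crop": crop,
                    "country": f"K{country:02d}",
                    "delta_yield_pct": max(dy, -100.0),
                    "delta_T_C": dT,
                    "co2_ppm": co2,
                    "co2_baseline_ppm": 360.0,
                    "delta_precip_pct": dP,
                    "adapt": adapt,
                    "baseline_T_C": tbar,
                    "pub_year": pub_year,
                    "method": method,
                    "adaptation_type": atype,
                    "model_id": model,
                }
            )
    return MetaDatabase(pd.DataFrame(rows), provenance=f"synthetic (seed {spec.seed})")


@dataclass
class GridGenSpec:
    """Generator settings for synthetic gridded layers."""

    nlat: int = 18
    nlon: int = 36
    n_countries: int = 12
    pattern_base: float = 0.55
    pattern_amplification: float = 1.4  # growth of warming ratio toward the poles
    t_equator: float = 28.0
    t_gradient: float = 32.0
    seasonal_amp: float = 15.0
    n_hotspots: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.nlat < 2 or self.nlon < 2:
            raise ValueError("grid resolution must be at least 2x2")


@dataclass
class GridBundle:
    """The gridded layers one run of the spatial pipeline needs."""

    pattern: xr.DataArray
    baseline_T: xr.DataArray
    monthly_T: xr.DataArray
    production: xr.DataArray
    irrigated_area: xr.DataArray
    rainfed_area: xr.DataArray
    country_mask: xr.DataArray
    calendar: CropCalendar


def gen_grids(spec: GridGenSpec) -> GridBundle:
    """Latitude-structured synthetic grids.

    The pattern field amplifies toward the poles and is normalized to an
    exact area-weighted global mean of one; baseline temperature falls with
    |latitude|; production concentrates in a few mid-latitude hotspots on
    top of a small background; the country mask tiles the grid into
    contiguous blocks; southern-hemisphere countries get a six-month-shifted
    crop calendar.
    """
    rng = np.random.default_rng(spec.seed)
    lat = np.linspace(-90, 90, spec.nlat + 1)
    lat = 0.5 * (lat[:-1] + lat[1:])  # cell centers
    lon = np.linspace(-180, 180, spec.nlon + 1)
    lon = 0.5 * (lon[:-1] + lon[1:])
    coords = {"lat": lat, "lon": lon}
    dims = ("lat", "lon")
    absl = np.abs(lat)[:, None] / 90.0
    ones = np.ones((spec.nlat, spec.nlon))

    pattern = spec.pattern_base + spec.pattern_amplification * absl**1.8 * ones
    pattern = pattern * (1.0 + 0.03 * rng.standard_normal(pattern.shape))
    pattern_da = xr.DataArray(pattern, coords=coords, dims=dims)
    pattern_da = pattern_da / float(
        (pattern_da * area_weights(pattern_da)).sum()
        / float(area_weights(pattern_da).sum())
    )

    baseline = spec.t_equator - spec.t_gradient * absl**1.3 * ones
    baseline = baseline + 0.3 * rng.standard_normal(baseline.shape)
    baseline_da = xr.DataArray(baseline, coords=coords, dims=dims)

    months = np.arange(1, 13)
    hemis = np.sign(lat)[:, None]
    amp = (spec.seasonal_amp * absl + 2.0) * ones
    monthly = np.stack(
        [
            baseline + hemis * amp * np.cos(2 * np.pi * (m - 7) / 12.0)
            for m in months
        ]
    )
    monthly_da = xr.DataArray(
        monthly, coords={"month": months, **coords}, dims=("month", "lat", "lon")
    )

    production = 0.01 * ones.copy()
    for _ in range(spec.n_hotspots):
        hlat = rng.uniform(-50, 50)
        hlon = rng.uniform(-170, 170)
        strength = rng.uniform(0.5, 2.0)
        d2 = ((lat[:, None] - hlat) / 20.0) ** 2 + ((lon[None, :] - hlon) / 30.0) ** 2
        production = production + strength * np.exp(-d2)
    production_da = xr.DataArray(production, coords=coords, dims=dims)

    irr_frac = rng.uniform(0.0, 1.0, size=production.shape)
    irrigated_da = xr.DataArray(production * irr_frac, coords=coords, dims=dims)
    rainfed_da = xr.DataArray(production * (1 - irr_frac), coords=coords, dims=dims)

    # contiguous lat x lon blocks as countries
    c_rows = max(1, int(np.floor(np.sqrt(spec.n_countries))))
    c_cols = int(np.ceil(spec.n_countries / c_rows))
    row_idx = np.minimum((np.arange(spec.nlat) * c_rows) // spec.nlat, c_rows - 1)
    col_idx = np.minimum((np.arange(spec.nlon) * c_cols) // spec.nlon, c_cols - 1)
    mask = row_idx[:, None] * c_cols + col_idx[None, :]
    mask = np.minimum(mask, spec.n_countries - 1)
    mask_da = xr.DataArray(mask.astype(float), coords=coords, dims=dims)

    windows = {"maize": (5, 9), "rice": (6, 10), "wheat": (10, 3), "soybean": (5, 10)}
    entries: dict = dict(windows)
    for country in range(spec.n_countries):
        sel = mask == country
        if sel.any() and lat[np.any(sel, axis=1)].mean() < 0:
            for crop, (p, h) in windows.items():
                entries[(crop, country)] = ((p + 5) % 12 + 1, (h + 5) % 12 + 1)
    calendar = CropCalendar(entries)

    return GridBundle(
        pattern=pattern_da,
        baseline_T=baseline_da,
        monthly_T=monthly_da,
        production=production_da,
        irrigated_area=irrigated_da,
        rainfed_area=rainfed_da,
        country_mask=mask_da,
        calendar=calendar,
    )


def gen_welfare_table(
    regions=FUND_REGIONS, seed: int = 0, severity: float = 1.0
) -> WelfareTable:
    """Synthetic regional welfare-change table at 1/2/3 degC of warming.

    Three components are drawn with the total imposed as their sum;
    magnitudes grow with the warming level; the direct productivity effect
    is negative and dominant, terms-of-trade effects vary in sign across
    regions (exporters gain, importers lose), and the allocative-efficiency
    effect is a small loss.  ``severity`` scales all components (0 gives the
    all-zero table).  Currency units are millions of dollars.
    """
    if not len(regions):
        raise ValueError("regions must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        vop = float(rng.uniform(2e4, 2e5))  # value of production of the 4 crops
        a = rng.uniform(0.010, 0.040)
        b = rng.uniform(0.005, 0.020)
        tot_sign = rng.normal(0.0, 1.0)
        for level in (1.0, 2.0, 3.0):
            prod = -severity * (a * level + b * level**2) * vop
            tot = severity * 0.010 * level * tot_sign * vop
            alloc = -severity * 0.003 * level * abs(rng.normal(0.0, 1.0)) * vop
            rows.append(
                {
                    "region": region,
                    "warming_C": level,
                    "productivity": prod,
                    "terms_of_trade": tot,
                    "allocative": alloc,
                    "total": prod + tot + alloc,
                    "value_of_production": vop,
                }
            )
    return WelfareTable(pd.DataFrame(rows))


def gen_legacy_ag_damages(regions=FUND_REGIONS) -> dict[str, DamageFunction]:
    """Synthetic stand-in for legacy IAM agricultural damage functions.

    Mild benefits at low warming turning to losses beyond about 3 degC --
    the qualitative shape of the agricultural sector in older IAM damage
    modules.  Quadratic in warming; not derived from any model output.
    """
    out = {}
    for i, r in enumerate(regions):
        a = 0.020 + 0.002 * (i % 5)
        b = -0.007
        out[r] = DamageFunction(region=r, method="quadratic", coeffs=(a, b))
    return out


def gen_other_sector_damages(
    regions=FUND_REGIONS, scale: float = 0.004
) -> dict[str, DamageFunction]:
    """Lumped non-agricultural damages: a quadratic fraction of GDP."""
    return {
        r: DamageFunction(region=r, method="quadratic", coeffs=(0.0, -scale))
        for r in regions
    }


def _emissions_path(years: np.ndarray, cfg: dict) -> np.ndarray:
    e = cfg["peak_gtco2"] / (
        1.0 + np.exp(-(years - cfg["midpoint_year"]) / cfg["timescale_yr"])
    )
    decline = years > cfg["decline_start"]
    if decline.any():
        horizon = years[-1]
        frac = (years[decline] - cfg["decline_start"]) / max(
            horizon - cfg["decline_start"], 1
        )
        floor = cfg["floor_frac"]
        e_at_start = cfg["peak_gtco2"] / (
            1.0 + np.exp(-(cfg["decline_start"] - cfg["midpoint_year"]) / cfg["timescale_yr"])
        )
        e[decline] = e_at_start * (1.0 - (1.0 - floor) * frac)
    return e


def gen_bau_scenario(
    base_year: int | None = None,
    horizon: int | None = None,
    seed: int = 0,
    regions=FUND_REGIONS,
    config: dict | None = None,
) -> Scenario:
    """The bundled business-as-usual scenario.

    Emissions follow a smooth config-driven rising-then-plateauing path
    (deterministic -- the calibration to about 4 degC above preindustrial in
    2100 does not depend on the seed), with the DICE-style exogenous
    non-CO2 forcing ramp.  GDP and population grow with declining growth
    rates; regional GDP shares and constant agricultural output shares are
    drawn once from the seed.
    """
    cfg = config or load_config()
    bau = cfg["bau"]
    base_year = base_year if base_year is not None else bau["base_year"]
    horizon = horizon if horizon is not None else bau["horizon"]
    if horizon <= base_year:
        raise ValueError("horizon must be after the base year")
    years = np.arange(base_year, horizon + 1)
    emissions = _emissions_path(years, bau["emissions"])

    fo = bau["forcing_other"]
    ramp = np.clip((years - base_year) / (fo["end_year"] - base_year), 0.0, 1.0)
    forcing_other = fo["start_wm2"] + (fo["end_wm2"] - fo["start_wm2"]) * ramp

    rng = np.random.default_rng(seed)
    econ = bau["economy"]
    t = years - base_year
    g = econ["gdp_growth0"] * np.exp(-econ["gdp_growth_decay"] * t)
    gdp_global = econ["gdp0_usd"] * np.exp(np.concatenate([[0.0], np.cumsum(g[:-1])]))
    shares = rng.dirichlet(np.full(len(regions), 5.0))
    gdp = pd.DataFrame(
        np.outer(gdp_global, shares), index=years, columns=list(regions)
    )
    pop_global = econ["pop0"] + (econ["pop_max"] - econ["pop0"]) * (
        1.0 - np.exp(-t / econ["pop_timescale_yr"])
    )
    pop_shares = rng.dirichlet(np.full(len(regions), 5.0))
    population = pd.DataFrame(
        np.outer(pop_global, pop_shares), index=years, columns=list(regions)
    )
    lo, hi = econ["ag_share_range"]
    ag = rng.uniform(lo, hi, size=len(regions))
    ag_share = pd.DataFrame(
        np.tile(ag, (len(years), 1)), index=years, columns=list(regions)
    )
    return Scenario(
        years=years,
        emissions=emissions,
        gdp=gdp,
        population=population,
        ag_share=ag_share,
        forcing_other=forcing_other,
    )
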