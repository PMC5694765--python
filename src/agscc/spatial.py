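"""Gridded yield changes at fixed levels of global warming.

Turns the fitted response surface into per-crop, per-cell yield shocks via
pattern scaling (local warming = fixed spatial ratio x global mean warming),
a fitted quadratic mapping from global warming to CO2 concentration, and the
adjusted prediction of :mod:`agscc.response_surface`.  Also provides the
generic operations used on gridded crop-model ensembles: warming-level year
extraction with an 11-year averaging window, irrigated/rainfed cell
selection, ensemble means, and production-weighted aggregation.

Grids are regular lat-lon :class:`xarray.DataArray` fields with cell-center
coordinates; area weights are proportional to cos(latitude); missing cells
are NaN.  No internal regridding is performed -- inputs must be aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .response_surface import (
    CROPS,
    C4_CROPS,
    MODERN_CO2_PPM,
    CoefficientSet,
    predict_yield_change_field,
)

#: A gridded field is simply a 2-D DataArray with "lat"/"lon" coordinates.
GridField = xr.DataArray


def _check_aligned(*fields: GridField) -> None:
    ref = fields[0]
    for f in fields[1:]:
        if f.shape != ref.shape:
            raise ValueError(f"grids not aligned: shapes {ref.shape} vs {f.shape}")
        for dim in ("lat", "lon"):
            if not np.allclose(ref[dim].values, f[dim].values):
                raise ValueError(f"grids not aligned on {dim}")


def area_weights(field: GridField) -> xr.DataArray:
    """cos(latitude) weights broadcast over the grid."""
    w = np.cos(np.deg2rad(field["lat"]))
    return w.broadcast_like(field)


def area_weighted_mean(field: GridField) -> float:
    """Area-weighted mean over unmasked (non-NaN) cells."""
    w = area_weights(field).values
    v = np.asarray(field.values, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("field is fully masked")
    return float((v[ok] * w[ok]).sum() / w[ok].sum())


def compute_pattern(
    future_mean: GridField, base_mean: GridField, global_warming: float
) -> GridField:
    """Pattern-scaling field: per-cell warming per degree of global warming.

    ``(future - base) / global_warming`` with the missing mask propagated.
    """
    if global_warming <= 0:
        raise ValueError("global_warming must be positive")
    _check_aligned(future_mean, base_mean)
    out = (future_mean - base_mean) / global_warming
    out.name = "pattern"
    return out


@dataclass
class WarmingCO2Map:
    """Quadratic map from global warming (degC) to CO2 concentration (ppm)."""

    c0: float
    c1: float
    c2: float
    adj_r2: float
    dof: int

    def __call__(self, delta_T) -> float | np.ndarray:
        t = np.asarray(delta_T, dtype=float)
        out = self.c0 + self.c1 * t + self.c2 * t**2
        return float(out) if out.ndim == 0 else out


def fit_warming_co2(pairs: Sequence[tuple[float, float]]) -> WarmingCO2Map:
    """Least-squares quadratic through (global dT, ppm) pairs.

    Stores the adjusted R-squared and dof = n - 3 as fit diagnostics.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise ValueError("need at least 3 (delta_T, ppm) pairs")
    t, c = arr[:, 0], arr[:, 1]
    X = np.column_stack([np.ones_like(t), t, t**2])
    coefs, _, _, _ = np.linalg.lstsq(X, c, rcond=None)
    resid = c - X @ coefs
    ss_res = float((resid**2).sum())
    ss_tot = float(((c - c.mean()) ** 2).sum())
    n = len(t)
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3) if n > 3 else r2
    else:
        adj = 1.0
    return WarmingCO2Map(
        c0=float(coefs[0]), c1=float(coefs[1]), c2=float(coefs[2]),
        adj_r2=float(adj), dof=n - 3,
    )


@dataclass
class CropCalendar:
    """Planting and harvest months per crop, optionally per country.

    ``windows`` maps either ``crop`` or ``(crop, country_code)`` to a
    ``(planting_month, harvest_month)`` pair (1-12, inclusive on both ends);
    windows may wrap the year boundary (e.g. November to March).
    """

    windows: Mapping

    def __post_init__(self):
        for key, (p, h) in self.windows.items():
            if not (1 <= p <= 12 and 1 <= h <= 12):
                raise ValueError(f"calendar months out of 1..12 for {key!r}")

    def months(self, crop: str, country=None) -> list[int]:
        if country is not None and (crop, country) in self.windows:
            p, h = self.windows[(crop, country)]
        elif crop in self.windows:
            p, h = self.windows[crop]
        else:
            raise KeyError(f"no calendar entry for crop {crop!r} (country {country!r})")
        return season_months(p, h)


def season_months(planting: int, harvest: int) -> list[int]:
    """Inclusive month sequence from planting to harvest, wrapping December."""
    if planting <= harvest:
        return list(range(planting, harvest + 1))
    return list(range(planting, 13)) + list(range(1, harvest + 1))


def baseline_growing_season_T(
    monthly_T: xr.DataArray,
    calendar: CropCalendar,
    production: GridField,
    country_mask: GridField,
    crops: Sequence[str] = CROPS,
) -> pd.DataFrame:
    """Country-crop baseline growing-season temperatures.

    For each cell: the mean of the monthly temperatures over the crop's
    planting-to-harvest window; then a production-weighted mean over the
    country's cells.  Countries with zero production of a crop are omitted
    (missing, not zero).  ``monthly_T`` has dims (month, lat, lon) with
    month coordinate 1..12; ``country_mask`` holds integer country codes.

    Returns a DataFrame indexed by (country, crop) with column
    ``baseline_T_C``.
    """
    _check_aligned(monthly_T.isel(month=0, drop=True), production, country_mask)
    codes = country_mask.values
    prod = production.values
    rows = []
    for country in np.unique(codes[np.isfinite(codes)]):
        country = int(country)
        in_country = codes == country
        for crop in crops:
            mons = calendar.months(crop, country)
            gs_mean = monthly_T.sel(month=mons).mean("month").values
            w = np.where(in_country, prod, 0.0)
            w = np.where(np.isfinite(gs_mean), w, 0.0)
            total = w.sum()
            if total <= 0:
                continue  # zero production: flagged missing by omission
            rows.append(
                {
                    "country": country,
                    "crop": crop,
                    "baseline_T_C": float((gs_mean * w)[w > 0].sum() / total),
                }
            )
    if not rows:
        raise ValueError("no country-crop combination has positive production")
    return pd.DataFrame(rows).set_index(["country", "crop"])


def broadcast_country_values(
    values: Mapping, country_mask: GridField
) -> GridField:
    """Paint per-country scalars onto the grid; unmapped countries -> NaN."""
    codes = country_mask.values
    out = np.full(codes.shape, np.nan)
    for country, val in values.items():
        out[codes == country] = val
    return xr.DataArray(out, coords=country_mask.coords, dims=country_mask.dims)


def gridded_yield_change(
    coefs: CoefficientSet,
    pattern: GridField,
    baseline_T: pd.DataFrame,
    country_mask: GridField,
    co2map: WarmingCO2Map,
    global_dT: float,
    crop: str,
    adapt: bool = True,
    c4_co2: bool = True,
    dT_max: float = 6.0,
) -> GridField:
    """Per-cell adjusted yield change (percent) at a global warming level.

    Local warming is ``pattern * global_dT``; the CO2 concentration comes
    from the fitted warming-CO2 quadratic (re-based against 360 ppm inside
    the prediction, so zero global warming gives the zero field); the
    precipitation term is evaluated at zero change.  Cells whose country has
    no baseline temperature for the crop are masked.  ``c4_co2=False``
    switches off CO2 fertilization for the C4 crop (maize) only.
    """
    if global_dT < 0 or global_dT > dT_max:
        raise ValueError(f"global_dT must be in [0, {dT_max}]")
    if global_dT > 3:
        warnings.warn(
            f"global_dT = {global_dT} is beyond the 3 degC calibration range",
            stacklevel=2,
        )
    _check_aligned(pattern, country_mask)
    per_country = baseline_T.xs(crop, level="crop")["baseline_T_C"].to_dict()
    tbar = broadcast_country_values(per_country, country_mask)
    local_dT = pattern.values * global_dT
    if crop in C4_CROPS and not c4_co2:
        co2_ppm = MODERN_CO2_PPM
    else:
        co2_ppm = float(co2map(global_dT))
    vals = predict_yield_change_field(
        coefs, crop, local_dT, tbar.values, co2_ppm, 0.0, adapt
    )
    vals = np.where(np.isfinite(tbar.values), vals, np.nan)
    out = xr.DataArray(vals, coords=pattern.coords, dims=pattern.dims)
    out.name = f"yield_change_{crop}"
    out.attrs.update(
        global_dT=global_dT,
        co2_ppm=co2_ppm,
        adapt=int(adapt),
        note=(
            "response-surface dT is change from the modern baseline; the "
            "pattern field supplies spatial shape only"
        ),
    )
    return out


def production_weighted_global(change: GridField, production: GridField) -> float:
    """Production-weighted mean yield change (percent) over unmasked cells."""
    _check_aligned(change, production)
    c = np.asarray(change.values, dtype=float)
    p = np.asarray(production.values, dtype=float)
    ok = np.isfinite(c) & np.isfinite(p)
    total = p[ok].sum()
    if total <= 0:
        raise ValueError("total production is zero over unmasked cells")
    return float((c[ok] * p[ok]).sum() / total)


def warming_level_window(
    annual_global_T: pd.Series, level: float, width: int = 11
) -> tuple[int, np.ndarray]:
    """First year a warming level is crossed, plus the averaging window.

    Returns ``(crossing_year, years)`` where ``years`` is the centered
    ``width``-year window around the crossing, for averaging any co-indexed
    field.  A window truncated by the series end is an error, never a silent
    shrink.
    """
    s = annual_global_T.astype(float)
    years = np.asarray(s.index, dtype=int)
    hit = np.flatnonzero(s.to_numpy() >= level)
    if hit.size == 0:
        raise ValueError(f"level not crossed: series never reaches {level}")
    i = int(hit[0])
    half = width // 2
    if i - half < 0 or i + half >= len(years):
        raise ValueError(
            f"{width}-year window around crossing year {years[i]} "
            "is truncated by the series bounds"
        )
    return int(years[i]), years[i - half : i + half + 1]


def smoothed_series(annual_global_T: pd.Series, window: int) -> pd.Series:
    """Optional centered running mean before crossing detection."""
    return annual_global_T.rolling(window, center=True, min_periods=1).mean()


def irrigation_select(
    irrigated_result: GridField,
    rainfed_result: GridField,
    irrigated_area: GridField,
    rainfed_area: GridField,
) -> GridField:
    """Per-cell choice of irrigated vs rainfed model output.

    The irrigated value is used only where irrigated crop area strictly
    exceeds rainfed area (ties go to rainfed).
    """
    _check_aligned(irrigated_result, rainfed_result, irrigated_area, rainfed_area)
    return xr.where(irrigated_area > rainfed_area, irrigated_result, rainfed_result)


def ensemble_mean(members: Sequence[GridField]) -> GridField:
    """Simple unweighted mean over crop-model x GCM ensemble members."""
    if not members:
        raise ValueError("empty ensemble")
    _check_aligned(*members)
    return xr.concat(members, dim="member").mean("member")
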