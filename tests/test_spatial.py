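"""Pattern scaling, warming-CO2 mapping, and gridded yield changes."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from agscc import synthdata as sd
from agscc.response_surface import YieldQuery, predict_yield_change
from agscc.spatial import (
    CropCalendar,
    area_weighted_mean,
    baseline_growing_season_T,
    compute_pattern,
    fit_warming_co2,
    gridded_yield_change,
    irrigation_select,
    ensemble_mean,
    production_weighted_global,
    season_months,
    warming_level_window,
)


def field(values, lats=None, lons=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    nlat, nlon = values.shape
    lats = lats if lats is not None else np.linspace(-60, 60, nlat)
    lons = lons if lons is not None else np.linspace(-150, 150, nlon)
    return xr.DataArray(values, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"))


class TestPattern:
    def test_uniform_warming_gives_unit_pattern(self):
        base = field(np.full((3, 4), 10.0))
        assert np.allclose(compute_pattern(base + 2.0, base, 2.0).values, 1.0)

    def test_no_warming_gives_zero_pattern(self):
        base = field(np.random.default_rng(0).normal(15, 5, (3, 4)))
        assert np.allclose(compute_pattern(base, base, 1.5).values, 0.0)

    def test_global_mean_conserved_at_equal_areas(self):
        # two cells at the same |latitude| have equal area weights
        f = field([[3.0, 1.0]], lats=[0.0], lons=[0.0, 90.0])
        pat = compute_pattern(f, field([[0.0, 0.0]], lats=[0.0], lons=[0.0, 90.0]), 2.0)
        assert pat.values.tolist() == [[1.5, 0.5]]
        assert area_weighted_mean(pat) == pytest.approx(1.0)

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            compute_pattern(field(np.zeros((2, 2))), field(np.zeros((3, 3))), 1.0)

    def test_mask_propagates(self):
        fut = field([[12.0, np.nan]])
        base = field([[10.0, 10.0]])
        pat = compute_pattern(fut, base, 2.0)
        assert np.isnan(pat.values[0, 1]) and pat.values[0, 0] == 1.0


class TestWarmingCO2:
    def test_exact_quadratic_recovered(self):
        c0, c1, c2 = 280.0, 60.0, 15.0
        t = np.linspace(0, 5, 20)
        m = fit_warming_co2(list(zip(t, c0 + c1 * t + c2 * t**2)))
        assert (m.c0, m.c1, m.c2) == pytest.approx((c0, c1, c2))
        assert m.adj_r2 == pytest.approx(1.0)

    def test_dof_is_n_minus_3(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 4, 101)
        m = fit_warming_co2(list(zip(t, 300 + 80 * t + rng.normal(0, 5, 101))))
        assert m.dof == 98

    def test_constant_pairs_flat(self):
        t = np.linspace(0, 3, 10)
        m = fit_warming_co2(list(zip(t, np.full(10, 400.0))))
        assert m.c1 == pytest.approx(0.0, abs=1e-9)
        assert m.c2 == pytest.approx(0.0, abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            fit_warming_co2([(0, 280), (1, 300)])


class TestGrowingSeason:
    def test_wraps_year_boundary(self):
        assert season_months(11, 3) == [11, 12, 1, 2, 3]

    def test_uniform_climate_any_calendar(self, grids):
        flat = xr.full_like(grids.monthly_T, 20.0)
        out = baseline_growing_season_T(
            flat, grids.calendar, grids.production, grids.country_mask
        )
        assert np.allclose(out["baseline_T_C"], 20.0)

    def test_production_weighted_country_mean(self):
        months = np.arange(1, 13)
        lats, lons = [10.0], [0.0, 30.0]
        monthly = xr.DataArray(
            np.tile(np.array([[10.0, 30.0]]), (12, 1, 1)),
            coords={"month": months, "lat": lats, "lon": lons},
            dims=("month", "lat", "lon"),
        )
        prod = field([[3.0, 1.0]], lats=lats, lons=lons)
        mask = field([[0.0, 0.0]], lats=lats, lons=lons)
        cal = CropCalendar({"wheat": (1, 12)})
        out = baseline_growing_season_T(monthly, cal, prod, mask, crops=("wheat",))
        assert out.loc[(0, "wheat"), "baseline_T_C"] == pytest.approx(15.0)

    def test_monthly_ramp_with_wrap(self):
        # monthly temps 1..12 degC, Nov-Mar window: mean of {11,12,1,2,3}
        months = np.arange(1, 13)
        lats, lons = [0.0], [0.0]
        monthly = xr.DataArray(
            months.reshape(12, 1, 1).astype(float),
            coords={"month": months, "lat": lats, "lon": lons},
            dims=("month", "lat", "lon"),
        )
        prod = field([[1.0]], lats=lats, lons=lons)
        mask = field([[0.0]], lats=lats, lons=lons)
        cal = CropCalendar({"wheat": (11, 3)})
        out = baseline_growing_season_T(monthly, cal, prod, mask, crops=("wheat",))
        assert out.loc[(0, "wheat"), "baseline_T_C"] == pytest.approx(5.8)

    def test_zero_production_country_missing(self):
        months = np.arange(1, 13)
        lats, lons = [0.0], [0.0, 30.0]
        monthly = xr.DataArray(
            np.full((12, 1, 2), 20.0),
            coords={"month": months, "lat": lats, "lon": lons},
            dims=("month", "lat", "lon"),
        )
        prod = field([[1.0, 0.0]], lats=lats, lons=lons)
        mask = field([[0.0, 1.0]], lats=lats, lons=lons)
        cal = CropCalendar({"rice": (5, 9)})
        out = baseline_growing_season_T(monthly, cal, prod, mask, crops=("rice",))
        assert (1, "rice") not in out.index  # missing, not zero
        assert (0, "rice") in out.index


@pytest.fixture(scope="module")
def grid_setup(grids, bau):
    from agscc.scc import run_scenario

    baseline = baseline_growing_season_T(
        grids.monthly_T, grids.calendar, grids.production, grids.country_mask
    )
    path = run_scenario(bau)
    co2map = fit_warming_co2(list(zip(path["dT"], path["co2_ppm"])))
    return baseline, co2map


class TestGriddedYield:

    def test_zero_warming_identity(self, grids, fitted, grid_setup):
        baseline, co2map = grid_setup
        for crop in ("wheat", "maize"):
            f = gridded_yield_change(
                fitted, grids.pattern, baseline, grids.country_mask,
                co2map, 0.0, crop,
            )
            assert np.nanmax(np.abs(f.values)) == 0.0

    def test_composition_matches_point_prediction(self, fitted, grid_setup):
        baseline, co2map = grid_setup
        pat = field([[1.2]], lats=[0.0], lons=[0.0])
        mask = field([[0.0]], lats=[0.0], lons=[0.0])
        bt = pd.DataFrame(
            {"baseline_T_C": [24.0]},
            index=pd.MultiIndex.from_tuples([(0, "rice")], names=["country", "crop"]),
        )
        got = gridded_yield_change(
            fitted, pat, bt, mask, co2map, 2.0, "rice", adapt=True
        )
        want = predict_yield_change(
            fitted,
            YieldQuery("rice", 1.2 * 2.0, 24.0, float(co2map(2.0)), 0.0, True),
        )
        assert got.values[0, 0] == pytest.approx(want, rel=1e-12)

    def test_clamp_floor(self, grids, grid_setup):
        baseline, co2map = grid_setup
        # a contrived surface with catastrophic losses still floors at -99
        extreme = sd.paperlike_coefficients()
        vals = extreme.values.copy()
        vals[[i for i, l in enumerate(extreme.labels) if l.startswith("dT2_tbar")]] = -3.0
        harsh = type(extreme)(values=vals, a_c3=100, a_c4=50)
        f = gridded_yield_change(
            harsh, grids.pattern, baseline, grids.country_mask, co2map, 3.0, "wheat"
        )
        assert np.nanmin(f.values) == -99.0

    def test_c4_co2_flag_only_affects_maize(self, grids, fitted, grid_setup):
        baseline, co2map = grid_setup
        args = (fitted, grids.pattern, baseline, grids.country_mask, co2map, 2.0)
        maize_on = gridded_yield_change(*args, "maize", c4_co2=True)
        maize_off = gridded_yield_change(*args, "maize", c4_co2=False)
        assert not np.allclose(maize_on.values, maize_off.values, equal_nan=True)
        wheat_on = gridded_yield_change(*args, "wheat", c4_co2=True)
        wheat_off = gridded_yield_change(*args, "wheat", c4_co2=False)
        assert np.allclose(wheat_on.values, wheat_off.values, equal_nan=True)

    def test_out_of_range_warming_rejected(self, grids, fitted, grid_setup):
        baseline, co2map = grid_setup
        with pytest.raises(ValueError):
            gridded_yield_change(
                fitted, grids.pattern, baseline, grids.country_mask,
                co2map, 7.0, "rice",
            )


class TestAggregation:
    def test_uniform_change(self):
        c = field(np.full((2, 2), -10.0))
        p = field(np.ones((2, 2)))
        assert production_weighted_global(c, p) == pytest.approx(-10.0)

    def test_weighted(self):
        c = field([[-20.0, 0.0]])
        p = field([[1.0, 3.0]])
        assert production_weighted_global(c, p) == pytest.approx(-5.0)

    def test_zero_weight_cells_masking_invariant(self):
        c = field([[-20.0, 0.0, -50.0]])
        p = field([[1.0, 3.0, 0.0]])
        masked = c.where(p > 0)
        assert production_weighted_global(c, p) == production_weighted_global(masked, p)

    def test_zero_total_production_errors(self):
        with pytest.raises(ValueError):
            production_weighted_global(field([[1.0]]), field([[0.0]]))


class TestWarmingLevelWindow:
    def test_linear_ramp_hand_computed(self):
        years = np.arange(2006, 2040)
        s = pd.Series(0.05 * (years - 2006), index=years)
        year, window = warming_level_window(s, 1.0)
        assert year == 2026
        assert window[0] == 2021 and window[-1] == 2031 and len(window) == 11

    def test_level_zero_is_first_year(self):
        s = pd.Series(np.linspace(0, 2, 30), index=np.arange(2000, 2030))
        year, window = warming_level_window(s, 0.0, width=1)
        assert year == 2000 and window.tolist() == [2000]

    def test_unreached_level_errors(self):
        s = pd.Series(np.linspace(0, 1, 50), index=np.arange(2000, 2050))
        with pytest.raises(ValueError, match="not crossed"):
            warming_level_window(s, 5.0)

    def test_truncated_window_errors_not_shrinks(self):
        years = np.arange(2000, 2010)
        s = pd.Series(np.linspace(0, 2, 10), index=years)
        with pytest.raises(ValueError, match="truncated"):
            warming_level_window(s, 1.9)


class TestIrrigationSelect:
    def test_all_rainfed_when_no_irrigation(self):
        irr, rain = field([[1.0, 2.0]]), field([[3.0, 4.0]])
        out = irrigation_select(irr, rain, field([[0.0, 0.0]]), field([[1.0, 1.0]]))
        assert np.array_equal(out.values, rain.values)

    def test_tie_goes_to_rainfed(self):
        irr, rain = field([[1.0]]), field([[3.0]])
        out = irrigation_select(irr, rain, field([[2.0]]), field([[2.0]]))
        assert out.values[0, 0] == 3.0

    def test_checkerboard_blend(self):
        irr, rain = field([[1.0, 1.0], [1.0, 1.0]]), field([[0.0, 0.0], [0.0, 0.0]])
        ia = field([[1.0, 0.0], [0.0, 1.0]])
        ra = field([[0.0, 1.0], [1.0, 0.0]])
        out = irrigation_select(irr, rain, ia, ra)
        assert out.values.tolist() == [[1.0, 0.0], [0.0, 1.0]]


def test_ensemble_mean_is_simple_mean():
    members = [field([[1.0, 2.0]]), field([[3.0, 6.0]])]
    out = ensemble_mean(members)
    assert out.values.tolist() == [[2.0, 4.0]]
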