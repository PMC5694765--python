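"""Response-surface estimation: design, fit, bootstrap, prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from agscc import synthdata as sd
from agscc.response_surface import (
    COEF_LABELS,
    CROPS,
    MetaDatabase,
    RankDeficientDesignError,
    YieldQuery,
    adjust_co2_delta,
    block_bootstrap,
    build_design_matrix,
    co2_response,
    fit_response_surface,
    predict_yield_change,
    run_specification_variant,
    select_co2_half_saturation,
)


def _tiny_db(n=25, seed=0, crops=CROPS):
    spec = sd.MetaGenSpec(
        seed=seed, n_studies=5, points_per_study=(n // 5, n // 5), rho=0.0, sd=5.0
    )
    db = sd.gen_meta_database(spec)
    return db.subset(db.records["crop"].isin(crops)) if crops != CROPS else db


class TestCO2Arithmetic:
    @pytest.mark.parametrize(
        "scenario,baseline,expected",
        [(560, 280, 200), (360, 360, 0), (460, 350, 100), (300, 280, 0)],
    )
    def test_rebased_to_modern_baseline(self, scenario, baseline, expected):
        # the study's own baseline is irrelevant; deltas are vs 360 ppm,
        # clamped at zero for scenarios below it
        assert adjust_co2_delta(scenario, baseline) == expected

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            adjust_co2_delta(-10, 360)
        with pytest.raises(ValueError):
            adjust_co2_delta(400, 0)

    @pytest.mark.parametrize(
        "dco2,a,expected", [(0, 100, 0.0), (100, 100, 0.5), (200, 100, 2 / 3)]
    )
    def test_saturation_curve_values(self, dco2, a, expected):
        assert co2_response(dco2, a) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_half_saturation_rejected(self):
        with pytest.raises(ValueError):
            co2_response(100, 0)

    @given(st.floats(0, 5000), st.floats(0, 5000), st.floats(1, 500))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_concave_bounded(self, x, y, a):
        lo, hi = sorted((x, y))
        flo, fhi = co2_response(lo, a), co2_response(hi, a)
        assert 0 <= flo <= fhi < 1
        mid = co2_response((lo + hi) / 2, a)
        assert mid >= (flo + fhi) / 2 - 1e-12  # concavity


class TestDesignMatrix:
    def test_shape_and_crop_dummies(self):
        db = _tiny_db(25, crops=("maize",))
        X, labels = build_design_matrix(db)
        assert X.shape == (len(db), 21) and labels == COEF_LABELS
        for crop in ("wheat", "rice", "soybean"):
            cols = [i for i, l in enumerate(labels) if l.endswith(f":{crop}")]
            assert np.all(X[:, cols] == 0)

    def test_zero_perturbation_row_is_zero(self):
        row = {
            "study_id": "s1", "crop": "wheat", "country": "K", "delta_yield_pct": 0.0,
            "delta_T_C": 0.0, "co2_ppm": 360.0, "co2_baseline_ppm": 360.0,
            "delta_precip_pct": 0.0, "adapt": False, "baseline_T_C": 20.0,
        }
        adapted = dict(row, adapt=True)
        db = MetaDatabase(pd.DataFrame([row, adapted]))
        X, labels = build_design_matrix(db)
        assert np.all(X[0] == 0)  # forced through the origin
        nz = np.flatnonzero(X[1])
        assert [labels[i] for i in nz] == ["adapt"] and X[1, nz[0]] == 1.0

    def test_unknown_crop_named_in_error(self):
        df = _tiny_db().records.copy()
        df.loc[3, "crop"] = "cassava"
        with pytest.raises(ValueError, match="cassava"):
            MetaDatabase(df)


class TestFit:
    def test_noiseless_recovery(self, noiseless_db, truth):
        fit = fit_response_surface(noiseless_db)
        np.testing.assert_allclose(fit.values, truth.values, atol=1e-5)
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.n_obs == len(noiseless_db)

    def test_matches_normal_equations_oracle(self):
        db = _tiny_db(30, seed=4)
        X, _ = build_design_matrix(db)
        y = db.records["delta_yield_pct"].to_numpy(float)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_response_surface(db)
        np.testing.assert_allclose(fit.values, oracle, rtol=1e-8)

    def test_residuals_retrievable(self, fitted, noisy_db):
        assert fitted.residuals is not None
        assert len(fitted.residuals) == len(noisy_db)
        X, _ = build_design_matrix(noisy_db)
        # OLS residuals are orthogonal to the design
        assert np.abs(X.T @ fitted.residuals).max() < 1e-6 * len(noisy_db)

    def test_missing_crop_is_rank_deficient(self):
        db = _tiny_db(40, seed=2)
        no_soy = db.subset(db.records["crop"] != "soybean")
        with pytest.raises(RankDeficientDesignError, match="soybean"):
            fit_response_surface(no_soy)

    def test_mean_bias_near_zero(self, truth):
        # light-weight parameter-recovery check; the acceptance suite runs
        # the full 200-replicate version
        reps = 40
        est = np.empty((reps, 21))
        for i in range(reps):
            db = sd.gen_meta_database(sd.MetaGenSpec(seed=7000 + i))
            est[i] = fit_response_surface(db).values
        t = (est.mean(0) - truth.values) / (est.std(0, ddof=1) / np.sqrt(reps))
        assert np.abs(t).max() < 4.0


class TestHalfSaturationSelection:
    def test_recovers_planted_values(self):
        # small noise: at the full study noise the C4 constant is weakly
        # identified because the amplitude compensates between curves
        db = sd.gen_meta_database(sd.MetaGenSpec(seed=31, sd=1.0))
        got = select_co2_half_saturation(db, [50, 100, 150], [25, 50, 100])
        assert got == (100, 50)

    def test_single_candidates_returned(self, noisy_db):
        assert select_co2_half_saturation(noisy_db, [120.0], [60.0]) == (120.0, 60.0)

    def test_noise_free_r2_is_one_at_truth(self, noiseless_db):
        fit = fit_response_surface(noiseless_db, 100.0, 50.0)
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-9)

    def test_rejects_nonpositive_candidates(self, noisy_db):
        with pytest.raises(ValueError):
            select_co2_half_saturation(noisy_db, [100, -5], [50])


class TestBlockBootstrap:
    def test_deterministic_under_seed(self, noisy_db):
        e1 = block_bootstrap(noisy_db, n_reps=20, seed=42)
        e2 = block_bootstrap(noisy_db, n_reps=20, seed=42)
        assert np.array_equal(e1.coef_matrix, e2.coef_matrix)

    def test_single_study_collapses_to_point_estimate(self):
        db = _tiny_db(30, seed=9)
        df = db.records.copy()
        df["study_id"] = "only_study"
        one = MetaDatabase(df)
        ens = block_bootstrap(one, n_reps=25, seed=3)
        point = fit_response_surface(one).values
        for q in (0.025, 0.5, 0.975):
            np.testing.assert_allclose(
                np.quantile(ens.coef_matrix, q, axis=0), point, rtol=1e-10
            )

    def test_quantiles_are_type7_empirical(self, noisy_db):
        ens = block_bootstrap(noisy_db, n_reps=30, seed=1)
        col = ens.coef_matrix[:, 0]
        assert ens.quantile(COEF_LABELS[0], 0.9) == np.quantile(col, 0.9)

    def test_quantile_needs_two_draws(self, noisy_db):
        ens = block_bootstrap(noisy_db, n_reps=1, seed=1)
        with pytest.raises(ValueError):
            ens.quantile("dP", 0.5)

    def test_model_blocking(self, noisy_db):
        ens = block_bootstrap(noisy_db, n_reps=10, seed=0, block_key="model_id")
        assert ens.block_key == "model_id" and ens.n_reps == 10

    def test_json_round_trip(self, noisy_db, tmp_path):
        ens = block_bootstrap(noisy_db, n_reps=5, seed=8)
        path = tmp_path / "ens.json"
        ens.to_json(path)
        back = type(ens).from_json(path)
        assert np.array_equal(back.coef_matrix, ens.coef_matrix)
        assert back.seed == 8


class TestPrediction:
    @pytest.mark.parametrize("adapt", [False, True])
    def test_origin(self, fitted, adapt):
        q = YieldQuery(crop="rice", delta_T_local=0.0, baseline_T=22.0,
                       co2_ppm=360.0, delta_precip=0.0, adapt=adapt)
        assert predict_yield_change(fitted, q) == pytest.approx(0.0, abs=1e-12)

    def test_clamped_at_minus_99(self, truth):
        # coefficients contrived so the raw prediction is far below -100
        vals = truth.values.copy()
        vals[list(truth.labels).index("dT2_tbar:soybean")] = -0.1
        harsh = type(truth)(values=vals, a_c3=truth.a_c3, a_c4=truth.a_c4)
        severe = YieldQuery(crop="soybean", delta_T_local=6.0, baseline_T=40.0,
                            co2_ppm=360.0)
        raw = harsh.predict_raw("soybean", 6.0, 40.0, 360.0, 0.0, False)
        assert raw < -100
        assert predict_yield_change(harsh, severe) == -99.0

    def test_adaptation_effect_is_interaction_only(self, fitted):
        t = 2.5
        on = predict_yield_change(
            fitted, YieldQuery("maize", t, 20.0, 360.0, 0.0, True)
        )
        off = predict_yield_change(
            fitted, YieldQuery("maize", t, 20.0, 360.0, 0.0, False)
        )
        assert on - off == pytest.approx(fitted.beta8 * t, rel=1e-10)

    def test_hotter_baselines_lose_more(self, truth):
        # warming is consistently more damaging where it is already hot;
        # checked on a surface fitted at low noise (the interaction signal
        # for minor crops is weaker than full-noise estimation error) and
        # on the calibrated truth itself
        db = sd.gen_meta_database(sd.MetaGenSpec(seed=88, sd=1.0))
        fitted = fit_response_surface(db)
        tbar = db.records["baseline_T_C"]
        cool, hot = tbar.quantile([0.25, 0.75])
        for coefs in (fitted, truth):
            for crop in CROPS:
                for t in (2.0, 3.0):
                    loss_hot = predict_yield_change(
                        coefs, YieldQuery(crop, t, hot, 360.0)
                    )
                    loss_cool = predict_yield_change(
                        coefs, YieldQuery(crop, t, cool, 360.0)
                    )
                    assert loss_hot <= loss_cool

    def test_coefficient_json_round_trip(self, fitted, tmp_path):
        path = tmp_path / "coefs.json"
        fitted.to_json(path)
        back = type(fitted).from_json(path)
        np.testing.assert_array_equal(back.values, fitted.values)
        assert (back.a_c3, back.a_c4) == (fitted.a_c3, fitted.a_c4)


class TestSpecificationVariants:
    def test_cubic_terms_insignificant_under_quadratic_truth(self):
        # truth is quadratic in dT, so added cubic terms should be noise
        tstats = []
        for seed in range(8):
            db = sd.gen_meta_database(sd.MetaGenSpec(seed=4000 + seed))
            fit = run_specification_variant(db, "cubic")
            tstats.extend(fit.tvalues[f"dT3:{c}"] for c in CROPS)
        tstats = np.abs(tstats)
        assert (tstats < 2.0).mean() > 0.8 and tstats.max() < 5.0

    def test_post2005_empty_sample_errors(self, noisy_db):
        df = noisy_db.records.copy()
        df["pub_year"] = 1999
        with pytest.raises(ValueError, match="2005"):
            run_specification_variant(MetaDatabase(df), "post2005")

    def test_post2005_filters(self, noisy_db):
        fit = run_specification_variant(noisy_db, "post2005")
        expected = int((noisy_db.records["pub_year"] >= 2005).sum())
        assert fit.n_obs == expected

    def test_single_method_interaction_rank_deficient(self, noisy_db):
        df = noisy_db.records.copy()
        df["method"] = "process"
        with pytest.raises(RankDeficientDesignError):
            run_specification_variant(MetaDatabase(df), "method_interaction")

    def test_adaptation_split_replaces_dummies(self, noisy_db):
        fit = run_specification_variant(noisy_db, "adaptation_split")
        assert "adapt" not in fit.params.index
        assert "adapt_cultivar" in fit.params.index

    def test_unknown_variant_rejected(self, noisy_db):
        with pytest.raises(ValueError):
            run_specification_variant(noisy_db, "bayesian")
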