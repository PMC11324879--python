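"""Vapour-pressure formula, feature selection, stacked-ensemble fitting and
grid prediction contracts."""

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LinearRegression

from cloudshift import temperature as tm
from cloudshift.raster import Grid, make_cube
from cloudshift.synthetic import SceneConfig, generate_scene, sample_stations


class TestSaturationVapourPressure:
    def test_zero_celsius_reference_value(self):
        assert tm.saturation_vapour_pressure(0.0) == pytest.approx(0.6108, abs=1e-12)

    def test_twenty_celsius_against_high_precision_oracle(self):
        # independent arbitrary-precision evaluation of the same closed form
        t = sympy.Rational(20)
        want = float(sympy.N(sympy.Rational(6108, 10000)
                             * sympy.exp(sympy.Rational(1727, 100) * t / (t + sympy.Rational(2373, 10))), 30))
        assert tm.saturation_vapour_pressure(20.0) == pytest.approx(want, rel=1e-12)

    def test_strictly_increasing(self):
        es = tm.saturation_vapour_pressure
        assert es(25.0) > es(15.0) > es(5.0)
        t = np.linspace(-30, 45, 200)
        assert np.all(np.diff(es(t)) > 0)

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            tm.saturation_vapour_pressure(-240.0)

    @settings(derandomize=True, max_examples=50)
    @given(t=st.floats(-100.0, 60.0), dt=st.floats(1e-6, 50.0))
    def test_strict_monotonicity_property(self, t, dt):
        es = tm.saturation_vapour_pressure
        assert es(t + dt) > es(t)


def station_frame(n, seed, noise=0.0, ndvi_effect=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "lst_day": rng.uniform(10, 35, n),
        "ndvi": rng.uniform(0, 1, n),
        "albedo": rng.uniform(0.05, 0.4, n),
        "lat": rng.uniform(-1, 1, n),
        "lon": rng.uniform(-1, 1, n),
    })
    y = df["lst_day"].to_numpy() - 2.0 + ndvi_effect * df["ndvi"].to_numpy() \
        + noise * rng.normal(size=n)
    return df, y


class TestForwardFeatureSelection:
    def blocks(self, n, seed=0):
        return np.random.default_rng(seed).integers(0, 6, n)

    def test_perfect_predictor_selected_first(self):
        df, y = station_frame(200, 1)
        df["target_copy"] = y
        sel = tm.spatial_forward_feature_selection(
            ["target_copy", "ndvi", "albedo"], df.assign(y=y), self.blocks(200),
            "y", estimator_factory=LinearRegression)
        assert "target_copy" in sel[:2]

    @pytest.mark.parametrize("seed", range(20))
    def test_pure_noise_candidates_never_selected(self, seed):
        # two genuinely informative features, two appended noise columns
        df, y = station_frame(150, seed, noise=0.3, ndvi_effect=4.0)
        rng = np.random.default_rng(seed + 1000)
        df["noise1"] = rng.normal(size=150)
        df["noise2"] = rng.normal(size=150)
        sel = tm.spatial_forward_feature_selection(
            ["lst_day", "ndvi", "noise1", "noise2"], df.assign(y=y),
            self.blocks(150, seed), "y", estimator_factory=LinearRegression)
        assert "noise1" not in sel and "noise2" not in sel
        assert set(sel) == {"lst_day", "ndvi"}

    def test_duplicated_feature_selected_at_most_once(self):
        df, y = station_frame(150, 3)
        df["lst_dup"] = df["lst_day"]
        sel = tm.spatial_forward_feature_selection(
            ["lst_day", "lst_dup", "ndvi"], df.assign(y=y), self.blocks(150),
            "y", estimator_factory=LinearRegression)
        assert not ("lst_day" in sel and "lst_dup" in sel)

    def test_single_block_rejected(self):
        df, y = station_frame(60, 0)
        with pytest.raises(ValueError, match="block"):
            tm.spatial_forward_feature_selection(
                ["lst_day", "ndvi"], df.assign(y=y), np.zeros(60, int), "y")


class TestFitStacked:
    def test_noiseless_linear_labels_recovered(self):
        df, y = station_frame(400, 5)
        model = tm.fit_stacked("tmax", df, df, y, n_estimators=100, seed=0)
        assert model.diagnostics["stacked"]["r2"] >= 0.99

    def test_null_labels_give_no_skill(self):
        """Labels independent of every feature: the stack shows no positive
        skill in any of 20 seeded repeats (held-out R² never exceeds 0.15;
        it may be mildly negative through ensemble prediction variance)."""
        r2s = []
        for seed in range(20):
            df, _ = station_frame(500, seed)
            y = np.random.default_rng(seed + 500).normal(size=500)
            model = tm.fit_stacked("tmax", df, df, y, n_estimators=30, seed=seed)
            r2s.append(model.diagnostics["stacked"]["r2"])
        assert max(r2s) < 0.15
        assert np.mean(r2s) < 0.05

    def test_stacking_does_not_hurt(self):
        df, y = station_frame(400, 9, noise=0.5)
        model = tm.fit_stacked("tmax", df, df, y, n_estimators=100, seed=1)
        base_best = min(model.diagnostics["terra"]["rmse"],
                        model.diagnostics["aqua"]["rmse"])
        assert model.diagnostics["stacked"]["rmse"] <= 1.05 * base_best

    def test_meta_consensus_close_to_base(self):
        df, y = station_frame(400, 5)
        model = tm.fit_stacked("tmax", df, df, y, n_estimators=100, seed=0)
        newdf, _ = station_frame(100, 6)
        stacked = model.predict(newdf, newdf)
        base = model.base_terra.predict(newdf[list(model.schema.names)].to_numpy())
        assert np.sqrt(np.mean((stacked - base) ** 2)) < 0.3

    def test_constant_labels_flagged_degenerate(self):
        df, _ = station_frame(100, 2)
        model = tm.fit_stacked("tmax", df, df, np.full(100, 21.0), seed=0)
        assert model.degenerate

    def test_too_few_rows_rejected(self):
        df, y = station_frame(30, 0)
        with pytest.raises(ValueError, match="50"):
            tm.fit_stacked("tmax", df, df, y)

    def test_serialisation_round_trip(self, tmp_path):
        df, y = station_frame(200, 7, noise=0.2)
        model = tm.fit_stacked("tmax", df, df, y, n_estimators=50, seed=0)
        path = tmp_path / "model.joblib"
        model.save(path)
        clone = tm.StackedModel.load(path)
        newdf, _ = station_frame(50, 8)
        np.testing.assert_array_equal(model.predict(newdf, newdf),
                                      clone.predict(newdf, newdf))


class TestPredictGrids:
    def make_cube(self, lst=30.0, hole=False):
        shape = (1, 4, 4)
        lst_arr = np.full(shape, float(lst))
        if hole:
            lst_arr[0, 1, 2] = np.nan
        template = Grid(np.zeros((4, 4)), pixel_size=1000.0)
        cube = make_cube({"lst_day": lst_arr,
                          "ndvi": np.full(shape, 0.5),
                          "albedo": np.full(shape, 0.2)}, [200307], template)
        cube["lat"] = (("y", "x"), np.zeros((4, 4)))
        cube["lon"] = (("y", "x"), np.zeros((4, 4)))
        return cube

    def fit_simple(self):
        df, y = station_frame(200, 4)
        return tm.fit_stacked("tmax", df, df, y, n_estimators=50, seed=0)

    def test_tmean_is_exact_arithmetic_mean(self):
        import xarray as xr
        tmax = xr.DataArray(np.full((2, 3, 3), 30.0), dims=("time", "y", "x"))
        tmin = xr.DataArray(np.full((2, 3, 3), 20.0), dims=("time", "y", "x"))
        tmean = tm.mean_air_temperature(tmax, tmin)
        np.testing.assert_array_equal(tmean.values, 25.0)

    def test_nodata_propagates(self):
        model = self.fit_simple()
        out = tm.predict_grids(model, self.make_cube(hole=True))
        assert np.isnan(out.values[0, 1, 2])
        assert np.isfinite(out.values[0, 0, 0])

    def test_missing_variable_named_in_error(self):
        model = self.fit_simple()
        cube = self.make_cube().drop_vars("albedo")
        with pytest.raises(KeyError, match="albedo"):
            tm.predict_grids(model, cube)

    def test_pixel_order_invariance(self):
        """Predictions are a pure per-pixel function of the features."""
        model = self.fit_simple()
        cube = self.make_cube(lst=28.0)
        out = tm.predict_grids(model, cube).values[0]
        assert np.allclose(out, out[0, 0])


class TestSceneRecovery:
    def test_zero_noise_annual_tmax_rmse(self):
        """On a noise-free scene the stacked model recovers annual-mean Tmax
        within 0.3 K RMSE."""
        scene = generate_scene(SceneConfig(grid_shape=(30, 30), noise_sd_K=0.0,
                                           nodata_frac=0.0, n_loss_events=6, seed=31))
        st = sample_stations(scene, 250, obs_noise_sd=0.0)
        cube = scene.cube
        codes = np.asarray(cube["time"].values)
        t_idx = {int(c): i for i, c in enumerate(codes)}
        rows_t = np.array([t_idx[y * 100 + m] for y, m in zip(st["year"], st["month"])])
        rr, cc = st["row"].to_numpy(), st["col"].to_numpy()
        feats = pd.DataFrame({v: cube[v].values[rows_t, rr, cc] if "time" in cube[v].dims
                              else cube[v].values[rr, cc]
                              for v in ("lst_day", "ndvi", "albedo", "lat", "lon")})
        model = tm.fit_stacked("tmax", feats, feats, st["tmax"].to_numpy(),
                               test_mask=(st["split"] == "test").to_numpy(),
                               n_estimators=100, seed=0)
        pred = tm.predict_grids(model, cube)
        annual = np.nanmean(pred.values[codes // 100 == 2003], axis=0)
        truth = np.nanmean(cube["air_tmax"].values[codes // 100 == 2003], axis=0)
        rmse = np.sqrt(np.nanmean((annual - truth) ** 2))
        assert rmse <= 0.3
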