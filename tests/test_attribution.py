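"""Stable-reference search, inverse-distance weighting, and the exactness of
the change decomposition."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cloudshift import attribution as at
from cloudshift.raster import Grid
from cloudshift.synthetic import SceneConfig, generate_scene


def bool_grid(mask, pixel_size=1000.0):
    return Grid(np.asarray(mask, bool), pixel_size=pixel_size)


def centre_loss_setup(n=5, pixel_size=1000.0, dem_vals=None):
    loss = np.zeros((n, n), bool)
    loss[n // 2, n // 2] = True
    stable = np.ones((n, n), bool)
    stable[n // 2, n // 2] = False
    dem = Grid(np.full((n, n), 1500.0) if dem_vals is None else np.asarray(dem_vals, float),
               pixel_size=pixel_size)
    return bool_grid(loss, pixel_size), bool_grid(stable, pixel_size), dem


class TestFindStableReferences:
    def test_flat_terrain_eight_neighbours(self):
        loss, stable, dem = centre_loss_setup(n=5)
        refs = at.find_stable_references(loss, stable, dem, radius_m=1500.0)
        assert refs.counts[0] == 8  # diagonal neighbours are within 1.5 km

    def test_reference_beyond_radius_excluded(self):
        loss = np.zeros((1, 8), bool)
        loss[0, 0] = True
        stable = np.zeros((1, 8), bool)
        stable[0, 6] = True          # 6 km away
        refs = at.find_stable_references(bool_grid(loss), bool_grid(stable),
                                         Grid(np.full((1, 8), 1500.0)),
                                         radius_m=5000.0, n_min=1)
        assert refs.counts[0] == 0 and refs.excluded[0]

    def test_elevation_envelope_excludes_reference(self):
        loss = np.zeros((1, 2), bool)
        loss[0, 0] = True
        stable = np.zeros((1, 2), bool)
        stable[0, 1] = True
        dem = Grid(np.array([[1550.0, 1700.0]]))
        emin = Grid(np.array([[1500.0, 1700.0]]))
        emax = Grid(np.array([[1600.0, 1700.0]]))
        refs = at.find_stable_references(bool_grid(loss), bool_grid(stable), dem,
                                         radius_m=5000.0, n_min=1,
                                         elev_min=emin, elev_max=emax)
        assert refs.counts[0] == 0  # 1700 m lies outside [1500, 1600]

    def test_overlapping_masks_rejected(self):
        m = bool_grid(np.ones((3, 3), bool))
        with pytest.raises(ValueError, match="disjoint"):
            at.find_stable_references(m, m, Grid(np.zeros((3, 3))))

    def test_empty_stable_mask_warns_and_excludes_all(self):
        loss, stable, dem = centre_loss_setup()
        empty = stable.with_values(np.zeros_like(stable.values, dtype=bool))
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            refs = at.find_stable_references(loss, empty, dem)
        assert any("stable" in str(x.message) for x in w)
        assert refs.excluded.all()


class TestIdwClimateSignal:
    def setup_refs(self, distances, n_min=1):
        refs = at.ReferenceSet(
            loss_rc=np.array([[0, 0]]),
            ref_indices=[np.arange(len(distances))],
            ref_distances=[np.asarray(distances, float)],
            n_min=n_min, radius_m=5000.0, grid_shape=(1, len(distances)))
        return refs

    def grid_of(self, values):
        return Grid(np.asarray(values, float).reshape(1, -1))

    def test_constant_field_returned_exactly(self):
        refs = self.setup_refs([800.0, 2500.0, 4100.0])
        out = at.idw_climate_signal(refs, self.grid_of([0.4, 0.4, 0.4]))
        assert out[0] == pytest.approx(0.4, abs=1e-15)

    def test_hand_computed_two_reference_case(self):
        # (d=1 km, 1.0) and (d=2 km, 0.0) -> (1/1) / (1/1 + 1/2) = 2/3
        refs = self.setup_refs([1000.0, 2000.0])
        out = at.idw_climate_signal(refs, self.grid_of([1.0, 0.0]))
        assert out[0] == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_matches_independent_weighted_mean_oracle(self, rng):
        d = rng.uniform(100, 5000, 12)
        v = rng.normal(0.3, 0.2, 12)
        refs = self.setup_refs(d)
        out = at.idw_climate_signal(refs, self.grid_of(v))
        assert out[0] == pytest.approx(np.average(v, weights=1.0 / d), rel=1e-12)

    def test_equidistant_references_give_plain_mean(self):
        refs = self.setup_refs([1000.0] * 4)
        out = at.idw_climate_signal(refs, self.grid_of([0.1, 0.2, 0.3, 0.4]))
        assert out[0] == pytest.approx(0.25, rel=1e-12)

    def test_zero_distance_uses_that_reference_directly(self):
        refs = self.setup_refs([0.0, 1000.0])
        out = at.idw_climate_signal(refs, self.grid_of([0.7, -5.0]))
        assert out[0] == 0.7

    def test_bounded_by_reference_extrema(self, rng):
        for _ in range(20):
            k = rng.integers(3, 10)
            d = rng.uniform(1, 5000, k)
            v = rng.normal(size=k)
            out = at.idw_climate_signal(self.setup_refs(d), self.grid_of(v))
            assert v.min() - 1e-12 <= out[0] <= v.max() + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(1.0, 5000.0), st.floats(-5.0, 5.0)),
                    min_size=1, max_size=12))
    def test_convex_combination_property(self, refs_list):
        d = np.array([r[0] for r in refs_list])
        v = np.array([r[1] for r in refs_list])
        out = at.idw_climate_signal(self.setup_refs(d), self.grid_of(v))
        assert v.min() - 1e-9 <= out[0] <= v.max() + 1e-9

    def test_insufficient_references_undefined(self):
        refs = self.setup_refs([1000.0], n_min=3)
        out = at.idw_climate_signal(refs, self.grid_of([1.0]))
        assert np.isnan(out[0])


class TestDecompose:
    def test_total_equals_cc_gives_zero_fcc(self):
        loss, stable, dem = centre_loss_setup()
        refs = at.find_stable_references(loss, stable, dem, radius_m=1500.0)
        total = dem.with_values(np.full((5, 5), 0.63))
        res = at.attribute("tmax", total, loss, stable, dem, refs=refs)
        r, c = refs.loss_rc[0]
        assert res.dT_fcc.values[r, c] == pytest.approx(0.0, abs=1e-15)

    def test_headline_style_arithmetic(self):
        loss, stable, dem = centre_loss_setup()
        refs = at.find_stable_references(loss, stable, dem, radius_m=1500.0)
        vals = np.full((5, 5), 0.63)
        vals[2, 2] = 2.0
        res = at.attribute("tmax", dem.with_values(vals), loss, stable, dem, refs=refs)
        assert res.dT_fcc.values[2, 2] == pytest.approx(2.0 - 0.63, rel=1e-12)

    def test_identity_exact_wherever_defined(self, noisy_scene):
        truth = noisy_scene.truth
        loss = truth.dem.with_values((truth.loss_year.values > 0)
                                     & ~truth.recovered.values.astype(bool))
        stable = truth.dem.with_values(truth.loss_year.values == 0)
        codes = np.asarray(noisy_scene.cube["time"].values)
        d_total = truth.dem.with_values(
            np.nanmean(noisy_scene.cube["air_tmax"].values[codes // 100 == 2022], axis=0)
            - np.nanmean(noisy_scene.cube["air_tmax"].values[codes // 100 == 2003], axis=0))
        res = at.attribute("tmax", d_total, loss, stable, truth.dem,
                           elev_min=truth.elev_min, elev_max=truth.elev_max)
        defined = np.isfinite(res.dT_cc.values)
        assert defined.sum() > 20
        np.testing.assert_allclose(res.dT_fcc.values[defined] + res.dT_cc.values[defined],
                                   res.dT_total.values[defined], rtol=0, atol=1e-12)

    def test_zero_noise_recovery_is_exact(self, quiet_scene):
        truth, cfg = quiet_scene.truth, quiet_scene.config
        loss = truth.dem.with_values((truth.loss_year.values > 0)
                                     & ~truth.recovered.values.astype(bool))
        stable = truth.dem.with_values(truth.loss_year.values == 0)
        codes = np.asarray(quiet_scene.cube["time"].values)
        d_total = truth.dem.with_values(
            np.nanmean(quiet_scene.cube["air_tmax"].values[codes // 100 == 2022], axis=0)
            - np.nanmean(quiet_scene.cube["air_tmax"].values[codes // 100 == 2003], axis=0))
        res = at.attribute("tmax", d_total, loss, stable, truth.dem,
                           elev_min=truth.elev_min, elev_max=truth.elev_max)
        defined = np.isfinite(res.dT_fcc.values)
        np.testing.assert_allclose(res.dT_fcc.values[defined],
                                   truth.true_dT_fcc.values[defined], atol=1e-9)
        np.testing.assert_allclose(res.dT_cc.values[defined],
                                   truth.true_dT_cc.values[defined], atol=1e-9)
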