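"""Predictor layers: QA screening, spectral indices, temporal stats, ETaP, CTI, LST anomaly."""

import datetime as dt

import numpy as np
import pytest

from gdemapper import predictors as pr
from gdemapper.raster_core import RasterError, RasterGrid
from .conftest import make_grid


def _obs(red=0.2, green=0.2, nir=0.4, swir1=0.3, lst=30.0, uncert=2.0,
         qa=0.0, shape=(3, 3), date=dt.date(2016, 8, 1), cloud_frac=0.0,
         lat0=0.001):
    def g(v, name):
        return make_grid(np.full(shape, float(v)), lat0=lat0, name=name)
    return pr.SceneObservation(
        date=date, red=g(red, "red"), green=g(green, "green"), nir=g(nir, "nir"),
        swir1=g(swir1, "swir1"), lst=g(lst, "lst"), lst_uncert=g(uncert, "lst_uncert"),
        qa=g(qa, "qa"), scene_cloud_fraction=cloud_frac,
    )


class TestQaScreen:
    def test_scene_over_20pct_cloud_dropped(self):
        kept = pr.qa_screen([_obs(cloud_frac=0.21), _obs(cloud_frac=0.20)])
        assert len(kept) == 1 and kept[0].scene_cloud_fraction == 0.20

    def test_cloud_pixel_masked_rest_intact(self):
        obs = _obs()
        obs.qa.values[0, 0] = pr.QA_CODES["cloud"]
        kept = pr.qa_screen([obs])[0]
        assert kept.nir.values[0, 0] == kept.nir.nodata
        assert kept.lst.values[0, 0] == kept.lst.nodata
        assert kept.nir.values[1, 1] == 0.4

    def test_lst_uncertainty_boundary(self):
        ok = _obs(uncert=5.0)
        bad = _obs(uncert=5.01)
        kept_ok, kept_bad = pr.qa_screen([ok]), pr.qa_screen([bad])
        assert np.all(kept_ok[0].lst.values == 30.0)      # 5.0 exactly retained
        assert np.all(kept_bad[0].lst.values == bad.lst.nodata)
        # reflectance untouched by the thermal rule
        assert np.all(kept_bad[0].nir.values == 0.4)


class TestSpectralIndex:
    def test_ndvi_symmetry_zero(self):
        out = pr.spectral_index(_obs(nir=0.3, red=0.3), "NDVI")
        assert np.allclose(out.values, 0.0)

    def test_ndvi_hand_value(self):
        out = pr.spectral_index(_obs(nir=0.5, red=0.1), "NDVI")
        assert out.values[0, 0] == pytest.approx(0.6667, abs=5e-5)

    def test_msavi_at_zero_reflectance(self):
        out = pr.spectral_index(_obs(nir=0.0, red=0.0), "MSAVI")
        assert np.allclose(out.values, 0.0)

    def test_formulas_match_direct_arithmetic(self):
        rng = np.random.default_rng(0)
        r, g, n, s = (rng.uniform(0.01, 0.9, (4, 4)) for _ in range(4))
        obs = _obs()
        obs.red, obs.green, obs.nir, obs.swir1 = (
            make_grid(r), make_grid(g), make_grid(n), make_grid(s))
        assert np.allclose(pr.spectral_index(obs, "NDVI").values, (n - r) / (n + r))
        assert np.allclose(pr.spectral_index(obs, "NDMI").values, (n - s) / (n + s))
        assert np.allclose(pr.spectral_index(obs, "NDWI").values, (g - n) / (g + n))
        msavi = (2 * n + 1 - np.sqrt((2 * n + 1) ** 2 - 8 * (n - r))) / 2
        assert np.allclose(pr.spectral_index(obs, "MSAVI").values, msavi)

    def test_bounded_for_positive_reflectance(self):
        rng = np.random.default_rng(1)
        obs = _obs()
        obs.red = make_grid(rng.uniform(0.001, 1, (5, 5)))
        obs.green = make_grid(rng.uniform(0.001, 1, (5, 5)))
        obs.nir = make_grid(rng.uniform(0.001, 1, (5, 5)))
        obs.swir1 = make_grid(rng.uniform(0.001, 1, (5, 5)))
        for kind in ("NDVI", "NDMI", "NDWI"):
            v = pr.spectral_index(obs, kind).values
            assert np.all(v >= -1) and np.all(v <= 1)
        assert np.all(pr.spectral_index(obs, "MSAVI").values <= 1)

    def test_zero_denominator_is_nodata(self):
        out = pr.spectral_index(_obs(nir=0.0, red=0.0), "NDVI")
        assert np.all(out.values == out.nodata)

    def test_unknown_kind_rejected(self):
        with pytest.raises(RasterError):
            pr.spectral_index(_obs(), "EVI")


class TestDrySeasonStats:
    def _dated(self, values_by_year, lat0=0.001, month=8):
        return [
            (dt.date(y, month, 15), make_grid(np.full((2, 2), v), lat0=lat0))
            for y, v in values_by_year.items()
        ]

    def test_constant_years_zero_cv(self):
        obs = self._dated({2015: 0.3, 2016: 0.3, 2017: 0.3})
        mean, cvar = pr.dry_season_stats(obs, [2015, 2016, 2017])
        assert np.allclose(mean.values, 0.3)
        assert np.allclose(cvar.values, 0.0)

    def test_sample_std_cv(self):
        obs = self._dated({2015: 0.2, 2016: 0.3, 2017: 0.4})
        mean, cvar = pr.dry_season_stats(obs, [2015, 2016, 2017])
        assert np.allclose(mean.values, 0.3)
        assert np.allclose(cvar.values, 0.1 / 0.3)  # n-1 denominator

    def test_population_cv_switch(self):
        obs = self._dated({2015: 0.2, 2016: 0.3, 2017: 0.4})
        _, cvar = pr.dry_season_stats(obs, [2015, 2016, 2017], ddof=0)
        expected = np.std([0.2, 0.3, 0.4]) / 0.3
        assert np.allclose(cvar.values, expected)

    def test_southern_hemisphere_window_excludes_august(self):
        # lat < 0: dry season is Jan-Mar, so an August scene contributes nothing
        obs = self._dated({2015: 0.5, 2016: 0.5}, lat0=-20.0, month=8)
        mean, _ = pr.dry_season_stats(obs, [2015, 2016])
        assert np.all(mean.values == mean.nodata)
        obs_jan = self._dated({2015: 0.5, 2016: 0.7}, lat0=-20.0, month=2)
        mean, _ = pr.dry_season_stats(obs_jan, [2015, 2016])
        assert np.allclose(mean.values, 0.6)

    def test_order_invariance_within_window(self):
        rng = np.random.default_rng(7)
        obs = []
        for y in (2015, 2016):
            for m in (7, 8, 9):
                obs.append((dt.date(y, m, 10), make_grid(rng.uniform(0, 1, (3, 3)))))
        fwd = pr.dry_season_stats(obs, [2015, 2016])
        rev = pr.dry_season_stats(obs[::-1], [2015, 2016])
        assert np.allclose(fwd[0].values, rev[0].values)
        assert np.allclose(fwd[1].values, rev[1].values)

    def test_near_zero_mean_cv_undefined(self):
        obs = self._dated({2015: 1e-9, 2016: -1e-9})
        _, cvar = pr.dry_season_stats(obs, [2015, 2016])
        assert np.all(cvar.values == cvar.nodata)


class TestEtap:
    def _monthly(self, annual_by_year, shape=(2, 2)):
        out = []
        for y, total in annual_by_year.items():
            for m in range(1, 13):
                out.append((dt.date(y, m, 15),
                            make_grid(np.full(shape, total / 12.0))))
        return out

    def test_groundwater_subsidy_ratio(self):
        t = self._monthly({2015: 500.0, 2016: 500.0})
        p = self._monthly({2015: 400.0, 2016: 400.0})
        out = pr.compute_etap(t, p, [2015, 2016])
        assert np.allclose(out.values, 1.25)

    def test_identity_ratio(self):
        t = self._monthly({2015: 300.0})
        out = pr.compute_etap(t, t, [2015])
        assert np.allclose(out.values, 1.0)

    def test_mean_of_annual_ratios_not_pooled(self):
        t = self._monthly({2015: 100.0, 2016: 300.0})
        p = self._monthly({2015: 200.0, 2016: 200.0})
        out = pr.compute_etap(t, p, [2015, 2016])
        assert np.allclose(out.values, 1.0)  # (0.5 + 1.5)/2, not 400/400 pooled

    def test_mismatched_calendars_rejected(self):
        t = self._monthly({2015: 100.0})
        p = self._monthly({2016: 100.0})
        with pytest.raises(RasterError, match="calendar"):
            pr.compute_etap(t, p, [2015])

    def test_zero_precip_year_excluded(self):
        t = self._monthly({2015: 100.0, 2016: 100.0})
        p = self._monthly({2015: 0.0, 2016: 200.0})
        out = pr.compute_etap(t, p, [2015, 2016])
        assert np.allclose(out.values, 0.5)  # only 2016 contributes


class TestCti:
    def test_inclined_plane_constant_along_contours(self):
        dem = make_grid(np.repeat(np.arange(7.0)[:, None] * 5.0, 7, axis=1) + 100.0)
        out = pr.compute_cti(dem)
        # contours run along rows: within-row spread is zero
        for i in range(1, 6):
            assert np.ptp(out.values[i, 1:-1]) < 1e-9

    def test_valley_floor_wetter_than_hillslope(self):
        # V-shaped valley draining down-row
        col = np.abs(np.arange(5) - 2) * 10.0
        dem_vals = col[None, :] + np.arange(5)[:, None] * -1.0 + 100.0
        out = pr.compute_cti(make_grid(dem_vals))
        for i in range(5):
            assert out.values[i, 2] > out.values[i, 0]
            assert out.values[i, 2] > out.values[i, 4]

    def test_flat_dem_finite_via_floor(self):
        out = pr.compute_cti(make_grid(np.full((4, 4), 50.0)))
        assert np.all(np.isfinite(out.values))

    def test_too_small_dem_rejected(self):
        with pytest.raises(RasterError):
            pr.compute_cti(make_grid(np.zeros((2, 5))))

    def test_accumulation_oracle_on_v_valley(self):
        # exhaustive D8 routing by hand: every pixel in the V drains toward
        # the center column, then down-row; upstream counts must match a
        # brute-force transitive closure of the flow graph
        col = np.abs(np.arange(5) - 2) * 10.0
        z = col[None, :] + np.arange(5)[:, None] * -1.0
        acc = pr._d8_accumulation(z)
        # brute force: follow flow from each cell, increment everything downstream
        expect = np.zeros_like(z, int)
        offsets = pr._D8_OFFSETS
        dists = [np.hypot(a, b) for a, b in offsets]
        def downstream(i, j):
            best, tgt = 0.0, None
            for k, (di, dj) in enumerate(offsets):
                ii, jj = i + di, j + dj
                if 0 <= ii < 5 and 0 <= jj < 5:
                    drop = (z[i, j] - z[ii, jj]) / dists[k]
                    if drop > best + 1e-15:
                        best, tgt = drop, (ii, jj)
            return tgt
        for i in range(5):
            for j in range(5):
                cur = downstream(i, j)
                while cur is not None:
                    expect[cur] += 1
                    cur = downstream(*cur)
        assert np.array_equal(acc, expect)


class TestLstAnomaly:
    def test_constant_field_zero_anomaly(self):
        lst = make_grid(np.full((9, 9), 31.0))
        water = np.zeros((9, 9), bool)
        out = pr.observation_lst_anomaly(lst, water, sides_px=(3, 5, 7))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_single_hot_pixel_hand_value(self):
        vals = np.full((9, 9), 20.0)
        vals[4, 4] += 3.0
        lst = make_grid(vals)
        out = pr.observation_lst_anomaly(lst, np.zeros((9, 9), bool), sides_px=(3, 5, 7))
        expected = np.mean([3.0 - 3.0 / n for n in (9, 25, 49)])
        assert out.values[4, 4] == pytest.approx(expected)
        # a direct neighbour sees slightly depressed temperature
        assert out.values[4, 5] < 0

    def test_window_sides_at_30m_pixels(self):
        assert pr.lst_window_sides_px() == (9, 91, 181)
        # even spans round up to odd so the window keeps a center pixel
        assert pr.lst_window_sides_px(90.0) == (3, 31, 61)

    def test_water_excluded_from_windows_and_output(self):
        vals = np.full((7, 7), 20.0)
        vals[3, 3] = 100.0  # a hot lake would bias neighbours if included
        water = np.zeros((7, 7), bool)
        water[3, 3] = True
        out = pr.observation_lst_anomaly(make_grid(vals), water, sides_px=(3, 3, 3))
        assert out.values[3, 3] == out.nodata
        assert np.allclose(out.values[out.values != out.nodata], 0.0, atol=1e-12)

    def test_near_zero_mean_on_noise_field(self):
        rng = np.random.default_rng(3)
        lst = make_grid(rng.normal(30.0, 2.0, (300, 300)))
        water = make_grid(np.zeros((300, 300)))
        out = pr.compute_lst_anomaly([(dt.date(2016, 8, 1), lst)], water, [2016],
                                     sides_px=(9, 91, 181))
        vals = out.values[out.values != out.nodata]
        assert abs(vals.mean()) < 0.05


class TestAssemble:
    def _layers(self):
        return {name: make_grid(np.zeros((2, 2))) for name in pr.LAYER_ORDER}

    def test_full_stack_assembles_in_canonical_order(self):
        stack = pr.assemble_predictors(self._layers())
        assert stack.names == pr.LAYER_ORDER

    def test_missing_layer_named(self):
        layers = self._layers()
        del layers["etap"]
        with pytest.raises(RasterError, match="etap"):
            pr.assemble_predictors(layers)

    def test_duplicate_layer_rejected(self):
        pairs = list(self._layers().items()) + [("ndvi_mean", make_grid(np.zeros((2, 2))))]
        with pytest.raises(RasterError, match="duplicate"):
            pr.assemble_predictors(pairs)


def test_signal_layers_separate_classes_on_default_scene(small_bundle, small_stack):
    """With contrast planted, ETaP exceeds 1 on GDEs (< 1 on matrix) and the
    thermal anomaly is negative on GDEs (non-negative on matrix)."""
    truth = small_bundle.truth.values == 1.0
    etap = small_stack.layers["etap"]
    ok = etap.valid_mask()
    assert etap.values[truth & ok].mean() > 1.0 > etap.values[~truth & ok].mean()
    anom = small_stack.layers["lst_anom"]
    ok = anom.valid_mask()
    assert anom.values[truth & ok].mean() < 0.0 < anom.values[~truth & ok].mean()
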