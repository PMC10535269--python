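"""Light-use-efficiency NPP model: component formulas, bounds, aggregation,
zoning, carbon totals, and point validation."""

import numpy as np
import pytest

from eumap import casa
from eumap import synthdata as sd
from eumap.errors import DegenerateInputError, EumapError, UndefinedMetricError
from eumap.raster import GridSpec, Raster


@pytest.fixture()
def lue():
    return casa.LueParameters(eps_max=0.389, ndvi_min=0.1, ndvi_max=0.8)


class TestFpar:
    def test_clamps_at_stretch_bounds(self, lue):
        assert casa.fpar(np.array([0.1]), lue)[0] == pytest.approx(0.001)
        assert casa.fpar(np.array([0.05]), lue)[0] == pytest.approx(0.001)
        assert casa.fpar(np.array([0.8]), lue)[0] == pytest.approx(0.95)
        assert casa.fpar(np.array([0.95]), lue)[0] == pytest.approx(0.95)

    def test_midway_blend_hand_value(self, lue):
        # alpha = 0.5 blend of the NDVI stretch and the SR stretch at NDVI = 0.5
        f_ndvi = (0.5 - 0.1) / (0.8 - 0.1) * (0.95 - 0.001) + 0.001
        sr = (1 + 0.5) / (1 - 0.5)
        sr_min = (1 + 0.1) / (1 - 0.1)
        sr_max = (1 + 0.8) / (1 - 0.8)
        f_sr = (sr - sr_min) / (sr_max - sr_min) * (0.95 - 0.001) + 0.001
        expected = 0.5 * (f_ndvi + f_sr)
        assert casa.fpar(np.array([0.5]), lue)[0] == pytest.approx(expected)

    def test_monotone_in_ndvi(self, lue):
        ndvi = np.linspace(-0.2, 0.95, 100)
        f = casa.fpar(ndvi, lue)
        assert np.all(np.diff(f) >= 0)

    def test_degenerate_stretch_rejected(self):
        with pytest.raises(Exception):
            casa.LueParameters(eps_max=0.389, ndvi_min=0.5, ndvi_max=0.5)


class TestApar:
    def test_zero_sol_gives_zero(self):
        assert np.all(casa.apar(np.zeros((3, 3)), np.full((3, 3), 0.5)) == 0)

    def test_direct_evaluation(self):
        assert casa.apar(np.array([400.0]), np.array([0.5]))[0] == pytest.approx(100.0)

    def test_upper_bound_from_fpar_cap(self, lue):
        sol = np.full(50, 321.0)
        a = casa.apar(sol, casa.fpar(np.linspace(-1, 1, 50), lue))
        assert np.all(a <= 0.475 * sol + 1e-12)

    def test_negative_sol_rejected(self):
        with pytest.raises(EumapError):
            casa.apar(np.array([-1.0]), np.array([0.5]))


class TestTemperatureStress:
    def test_te1_hand_value(self):
        te1, _ = casa.temperature_stress(np.array([15.0]), 20.0)
        assert te1[0] == pytest.approx(0.8 + 0.4 - 0.2)

    def test_te2_peaks_near_optimum(self):
        t_grid = np.linspace(-40, 60, 2001)
        te1, te2 = casa.temperature_stress(t_grid, 20.0)
        t_at_max = t_grid[np.argmax(te2)]
        te2_at_opt = casa.temperature_stress(np.array([20.0]), 20.0)[1][0]
        assert abs(t_at_max - 20.0) < 2.5          # maximum sits near Topt
        assert te2.max() - te2_at_opt < 0.01       # ... and is nearly attained there
        assert te2.max() <= casa.TE2_CEILING

    def test_te2_vanishes_in_deep_cold(self):
        _, te2 = casa.temperature_stress(np.array([-60.0]), 20.0)
        assert te2[0] < 1e-4

    def test_nonnegative(self):
        te1, te2 = casa.temperature_stress(np.linspace(-50, 60, 200), -40.0)
        assert te1.min() >= 0 and te2.min() >= 0


class TestWaterStress:
    def test_bounds(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 300, 500)
        t = rng.uniform(-5, 35, 500)
        heat = np.full(500, 60.0)
        we = casa.water_stress(p, t, heat)
        assert np.all((we >= 0.5) & (we <= 1.0))

    def test_dry_pixel_is_half(self):
        we = casa.water_stress(np.array([0.0]), np.array([-5.0]), np.array([0.0]))
        assert we[0] == 0.5

    def test_wetter_is_less_stressed(self):
        heat = np.full(2, 60.0)
        t = np.full(2, 20.0)
        dry, wet = casa.water_stress(np.array([5.0, 250.0]), t, heat)
        assert wet > dry

    def test_ratio_form(self):
        # We = 0.5 + 0.5 * EET/PET: a saturated pixel reaches the upper clamp
        we = casa.water_stress(np.array([1000.0]), np.array([25.0]), np.array([80.0]))
        assert we[0] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def run():
    truth = sd.default_truth(seed=4, shape=(48, 48))
    labels = sd.make_label_raster(truth)
    climate = sd.generate_climate(truth)
    ndvi = sd.generate_ndvi_series(truth, labels)
    eps = {cid: casa.EPS_MAX_DEFAULTS.get(name, 0.389)
           for cid, name in sd.CLASS_NAMES.items()}
    params = casa.auto_configure(ndvi, labels, eps)
    grid = casa.CasaModel(labels, params).run(ndvi, climate)
    return truth, labels, climate, ndvi, grid


class TestNpp:
    def test_hand_example(self):
        assert casa.npp_from_components(100.0, 1.0, 0.9, 0.8, 0.389) \
            == pytest.approx(28.008, abs=1e-9)

    def test_any_zero_stress_zeroes_npp(self):
        assert casa.npp_from_components(100.0, 0.0, 0.9, 0.8, 0.389) == 0.0
        assert casa.npp_from_components(100.0, 1.0, 0.9, 0.0, 0.389) == 0.0

    def test_annual_is_sum_of_monthly(self, run):
        *_, grid = run
        np.testing.assert_allclose(grid.annual, grid.monthly.sum(axis=0), rtol=1e-6)

    def test_nonnegative_and_bounded(self, run):
        truth, labels, climate, ndvi, grid = run
        assert grid.monthly.min() >= 0
        eps_max = max(p.eps_max for p in grid.params.values())
        te1_max = 0.8 + 0.02 * grid.t_opt - 0.0005 * grid.t_opt ** 2
        bound = 0.5 * climate.sol * 0.95 * np.maximum(te1_max, 0) \
            * casa.TE2_CEILING * 1.0 * eps_max
        assert np.all(grid.monthly <= bound + 1e-9)

    def test_zero_sol_zeroes_npp(self, run):
        truth, labels, climate, ndvi, grid = run
        dark = sd.ClimateStack(climate.months, np.zeros_like(climate.sol),
                               climate.temp, climate.precip, climate.grid)
        out = casa.CasaModel(labels, grid.params).run(ndvi, dark)
        assert np.all(out.monthly == 0)

    def test_incomplete_year_rejected(self, run):
        truth, labels, climate, ndvi, grid = run
        short = sd.ClimateStack(climate.months[:6], climate.sol[:6],
                                climate.temp[:6], climate.precip[:6], climate.grid)
        with pytest.raises(EumapError):
            casa.CasaModel(labels, grid.params).run(ndvi, short)


class TestZoningAndCarbon:
    def test_classify_npp_grades_ascending(self):
        g = GridSpec(0, 1000, 16)
        rng = np.random.default_rng(1)
        arr = np.concatenate([rng.normal(m, 5, 200) for m in (50, 200, 400, 700)])
        raster = Raster(arr.reshape(20, 40), g)
        grades, breaks = casa.classify_npp(raster)
        assert list(breaks) == sorted(breaks)
        means = [raster.data[grades.data == k].mean() for k in (1, 2, 3, 4)]
        assert means == sorted(means)

    def test_constant_raster_rejected(self):
        with pytest.raises(DegenerateInputError):
            casa.classify_npp(Raster(np.full((5, 5), 3.0), GridSpec(0, 100, 16)))

    def test_total_carbon_unit_conversion(self):
        arr = np.array([[500.0]])
        assert casa.total_carbon(arr, np.array([[True]]), 256.0) \
            == pytest.approx(0.128)

    def test_total_carbon_empty_mask_and_linearity(self):
        arr = np.full((4, 4), 100.0)
        mask = np.zeros((4, 4), dtype=bool)
        assert casa.total_carbon(arr, mask, 256.0) == 0.0
        mask[0] = True
        t1 = casa.total_carbon(arr, mask, 256.0)
        t2 = casa.total_carbon(arr, mask, 512.0)
        assert t2 == pytest.approx(2 * t1)


class TestValidate:
    def make(self, est, ref):
        g = GridSpec(0, 1000, 16)
        return Raster(est, g), Raster(ref, g)

    def test_identity(self):
        arr = np.random.default_rng(0).uniform(0, 500, (20, 20))
        est, ref = self.make(arr, arr.copy())
        res = casa.validate(est, ref, n_points=30, seed=1)
        assert res.rmse == 0.0 and res.r == pytest.approx(1.0)

    def test_constant_offset(self):
        arr = np.random.default_rng(0).uniform(0, 500, (20, 20))
        est, ref = self.make(arr + 10.0, arr)
        res = casa.validate(est, ref, n_points=30, seed=1)
        assert res.rmse == pytest.approx(10.0) and res.r == pytest.approx(1.0)

    def test_anticorrelated(self):
        arr = np.random.default_rng(0).uniform(0, 500, (20, 20))
        est, ref = self.make(arr, -arr)
        res = casa.validate(est, ref, n_points=30, seed=1)
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        est, ref = self.make(np.full((10, 10), 5.0),
                             np.random.default_rng(0).uniform(0, 1, (10, 10)))
        with pytest.raises(UndefinedMetricError):
            casa.validate(est, ref, n_points=20, seed=0)

    def test_points_logged_and_deterministic(self):
        arr = np.random.default_rng(0).uniform(0, 500, (20, 20))
        est, ref = self.make(arr, arr + 1)
        a = casa.validate(est, ref, n_points=10, seed=5)
        b = casa.validate(est, ref, n_points=10, seed=5)
        assert len(a.points) == 10
        assert (a.points == b.points).all().all()


def test_auto_configure_uses_percentiles():
    g = GridSpec(0, 1000, 16)
    veg = Raster(np.ones((10, 10), dtype=np.uint8), g)
    series = Raster(np.tile(np.linspace(0, 1, 100).reshape(1, 10, 10), (12, 1, 1)), g)
    params = casa.auto_configure(series, veg, {1: 0.5})
    assert params[1].ndvi_min == pytest.approx(np.percentile(series.data, 5))
    assert params[1].ndvi_max == pytest.approx(np.percentile(series.data, 95))
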