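"""Maximum-entropy SDM: normalization, recovery of the generating driver,
regularization behaviour, AUC, importance, zoning and area accounting."""

import numpy as np
import pandas as pd
import pytest

from eumap import sdm
from eumap import synthdata as sd
from eumap.errors import ConfigurationError, EumapError, SchemaError
from eumap.raster import GridSpec, Raster


@pytest.fixture(scope="module")
def occ_inputs():
    truth = sd.default_truth(seed=6)
    return sd.generate_sdm_inputs(truth, 60, 2000)


@pytest.fixture(scope="module")
def fitted(occ_inputs):
    occ, _, _ = occ_inputs
    return sdm.fit(occ)


def toy_occurrences(n_p=40, n_b=400, seed=0, informative=True):
    """One driver ('BIO17') plus one noise covariate ('BIO1')."""
    rng = np.random.default_rng(seed)
    bg = pd.DataFrame({"x": rng.uniform(0, 100, n_b), "y": rng.uniform(0, 100, n_b),
                       "BIO1": rng.normal(14, 1.5, n_b),
                       "BIO17": rng.normal(28, 10, n_b)})
    if informative:
        pres_b17 = rng.normal(45, 5, n_p)
    else:
        pres_b17 = rng.normal(28, 10, n_p)
    pres = pd.DataFrame({"x": rng.uniform(0, 100, n_p), "y": rng.uniform(0, 100, n_p),
                         "BIO1": rng.normal(14, 1.5, n_p), "BIO17": pres_b17})
    return sd.OccurrenceSet(presence=pres, background=bg,
                            covariate_names=("BIO1", "BIO17"))


class TestFit:
    def test_raw_output_sums_to_one_over_background(self, fitted, occ_inputs):
        occ, _, _ = occ_inputs
        assert fitted.raw(occ.background).sum() == pytest.approx(1.0, rel=1e-9)

    def test_constant_covariates_give_uniform_model(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({"x": rng.uniform(0, 10, 200), "y": rng.uniform(0, 10, 200),
                           "BIO1": np.full(200, 5.0)})
        pres = bg.head(20).copy()
        occ = sd.OccurrenceSet(presence=pres, background=bg, covariate_names=("BIO1",))
        model = sdm.fit(occ)
        p = model.logistic(bg)
        assert np.ptp(p) < 1e-9  # spatially constant logistic output

    def test_recovers_driver_sign(self):
        occ = toy_occurrences()
        model = sdm.fit(occ)
        # the gain attribution identifies the generating driver
        imp = sdm.variable_importance(model, occ)
        assert imp.iloc[0]["variable"] == "BIO17"
        # and presence scores exceed background scores
        assert model.scores(occ.presence).mean() > model.scores(occ.background).mean()

    def test_huge_regularization_zeroes_weights(self):
        occ = toy_occurrences()
        model = sdm.fit(occ, sdm.MaxentConfig(beta=1e6))
        assert np.all(model.lam == 0.0)

    def test_l1_path_monotone_in_beta(self):
        occ = toy_occurrences()
        nnz = [int((sdm.fit(occ, sdm.MaxentConfig(beta=b)).lam != 0).sum())
               for b in (0.5, 2.0, 8.0, 32.0, 1e3)]
        assert nnz == sorted(nnz, reverse=True)

    def test_gain_is_nonnegative_and_deterministic(self, occ_inputs):
        occ, _, _ = occ_inputs
        a = sdm.fit(occ)
        b = sdm.fit(occ)
        assert a.gain >= 0
        np.testing.assert_array_equal(a.lam, b.lam)

    def test_nonfinite_covariates_rejected(self):
        occ = toy_occurrences()
        occ.presence.loc[0, "BIO17"] = np.nan
        with pytest.raises(EumapError):
            sdm.fit(occ)


class TestRocAuc:
    def test_perfect_separation(self):
        assert sdm.roc_auc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_reversed_scores_complement(self):
        assert sdm.roc_auc([0, 1, 2], [3, 4, 5]) == 0.0

    def test_all_ties_half(self):
        assert sdm.roc_auc([1, 1], [1, 1, 1]) == 0.5

    def test_random_scores_near_half(self):
        # permutation null: AUC is a rank statistic with known variance
        rng = np.random.default_rng(0)
        n_p, n_b = 50, 500
        aucs = [sdm.roc_auc(rng.normal(size=n_p), rng.normal(size=n_b))
                for _ in range(50)]
        sigma = np.sqrt((n_p + n_b + 1) / (12 * n_p * n_b))
        assert abs(np.mean(aucs) - 0.5) < 3 * sigma / np.sqrt(50)

    def test_invariant_under_monotone_transform(self, fitted, occ_inputs):
        occ, _, _ = occ_inputs
        sp = fitted.scores(occ.presence)
        sb = fitted.scores(occ.background)
        a0 = sdm.roc_auc(sp, sb)
        a1 = sdm.roc_auc(np.exp(2 * sp) + 7, np.exp(2 * sb) + 7)
        assert a0 == pytest.approx(a1)

    def test_empty_presences_rejected(self):
        with pytest.raises(EumapError):
            sdm.roc_auc([], [1, 2])


class TestImportance:
    def test_contributions_sum_to_100(self, fitted, occ_inputs):
        occ, _, _ = occ_inputs
        imp = sdm.variable_importance(fitted, occ)
        assert imp["percent_contribution"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_informative_variable_dominates(self):
        # one real driver among pure-noise covariates
        rng = np.random.default_rng(3)
        n_b, n_p = 600, 50
        cols_bg = {f"N{i}": rng.normal(0, 1, n_b) for i in range(8)}
        cols_p = {f"N{i}": rng.normal(0, 1, n_p) for i in range(8)}
        bg = pd.DataFrame({"x": np.zeros(n_b), "y": np.zeros(n_b),
                           "DRV": rng.normal(0, 1, n_b), **cols_bg})
        pres = pd.DataFrame({"x": np.zeros(n_p), "y": np.zeros(n_p),
                             "DRV": rng.normal(2.0, 0.5, n_p), **cols_p})
        occ = sd.OccurrenceSet(pres, bg, covariate_names=("DRV",) + tuple(cols_bg))
        model = sdm.fit(occ)
        imp = sdm.variable_importance(model, occ)
        assert imp.iloc[0]["variable"] == "DRV"
        assert imp.iloc[0]["percent_contribution"] > 50.0

    def test_permutation_mode_identifies_driver(self):
        occ = toy_occurrences()
        model = sdm.fit(occ)
        imp = sdm.variable_importance(model, occ, "permutation", seed=0)
        assert imp.iloc[0]["variable"] == "BIO17"
        assert imp["permutation_importance"].sum() == pytest.approx(100.0, abs=0.1)

    def test_jackknife_driver_gain(self):
        occ = toy_occurrences()
        model = sdm.fit(occ)
        jk = sdm.variable_importance(model, occ, "jackknife").set_index("variable")
        assert jk.loc["BIO17", "gain_with_only"] > jk.loc["BIO1", "gain_with_only"]

    def test_unknown_mode_rejected(self, fitted, occ_inputs):
        occ, _, _ = occ_inputs
        with pytest.raises(EumapError):
            sdm.variable_importance(fitted, occ, "shapley")


class TestPredictRaster:
    def test_monotone_single_driver_and_nodata(self):
        occ = toy_occurrences()
        model = sdm.fit(occ)
        g = GridSpec(0, 1000, 1000)
        b17 = np.tile(np.linspace(0, 60, 30), (4, 1))
        b1 = np.full((4, 30), 14.0)
        b17[0, 0] = np.nan
        stack = Raster(np.stack([b1, b17]), g, band_names=("BIO1", "BIO17"))
        p = sdm.predict_logistic(model, stack)
        assert np.isnan(p.data[0, 0])
        row = p.data[2]
        assert row[-1] > row[0]  # suitability rises along the driver gradient
        assert np.nanmin(p.data) >= 0 and np.nanmax(p.data) <= 1

    def test_missing_layer_rejected(self, fitted):
        g = GridSpec(0, 1000, 1000)
        stack = Raster(np.zeros((1, 3, 3)), g, band_names=("BIO1",))
        with pytest.raises(SchemaError):
            sdm.predict_logistic(fitted, stack)


class TestReplicates:
    def test_bootstrap_split_sizes_and_determinism(self, occ_inputs):
        occ, _, _ = occ_inputs
        reps = sdm.bootstrap_replicates(occ, n_replicates=3, seed=1)
        assert all(r.n_train == 45 and r.n_test == 15 for r in reps)
        again = sdm.bootstrap_replicates(occ, n_replicates=3, seed=1)
        assert [r.auc_test for r in reps] == [r.auc_test for r in again]


class TestZoning:
    def test_fixed_breaks_interval_lookup(self):
        g = GridSpec(0, 1000, 1000)
        p = Raster(np.array([[0.1, 0.2], [0.4, 0.6]]), g)
        grades, breaks = sdm.classify_suitability(p, "fixed_breaks")
        np.testing.assert_array_equal(grades.data, [[1, 2], [3, 4]])
        assert breaks == [0.16, 0.35, 0.5]

    def test_boundary_values_half_open(self):
        g = GridSpec(0, 1000, 1000)
        p = Raster(np.array([[0.16, 0.35, 0.5, 0.159]]), g)
        grades, _ = sdm.classify_suitability(p, "fixed_breaks")
        np.testing.assert_array_equal(grades.data, [[2, 3, 4, 1]])

    def test_all_below_first_break_single_grade(self):
        g = GridSpec(0, 1000, 1000)
        p = Raster(np.full((3, 3), 0.05), g)
        grades, _ = sdm.classify_suitability(p, "fixed_breaks")
        assert set(np.unique(grades.data)) == {1}

    def test_natural_breaks_on_clusters(self):
        g = GridSpec(0, 1000, 1000)
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.uniform(lo, lo + 0.02, 25)
                               for lo in (0.05, 0.3, 0.6, 0.9)])
        p = Raster(vals.reshape(10, 10), g)
        grades, _ = sdm.classify_suitability(p, "natural_breaks")
        # clusters map to grades 1..4 in order
        order = [grades.data.ravel()[vals.argsort()][i] for i in (0, 30, 55, 80)]
        assert order == [1, 2, 3, 4]

    def test_constant_natural_breaks_rejected(self):
        g = GridSpec(0, 1000, 1000)
        with pytest.raises(Exception):
            sdm.classify_suitability(Raster(np.full((4, 4), 0.5), g), "natural_breaks")

    def test_unknown_method_rejected(self):
        g = GridSpec(0, 1000, 1000)
        with pytest.raises(ConfigurationError):
            sdm.classify_suitability(Raster(np.zeros((2, 2)), g), "quantiles")


class TestArea:
    def test_pixel_count_times_resolution_squared(self):
        g = GridSpec(0, 1000, 1000)
        grades = Raster(np.ones((10, 10), dtype=np.uint8), g)
        assert sdm.area_by_class(grades, 1.0) == {1: 100.0}

    def test_resolution_scaling(self):
        g = GridSpec(0, 1000, 500)
        arr = np.ones((10, 10), dtype=np.uint8)
        arr[:5] = 2
        grades = Raster(arr, g)
        areas = sdm.area_by_class(grades, 0.5)
        assert areas == {1: 12.5, 2: 12.5}
        assert sum(areas.values()) == pytest.approx(0.25 * 100)
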