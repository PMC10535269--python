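"""Generator correctness: spectra, spacing, splits, climate, SDM inputs."""

import numpy as np
import pandas as pd
import pytest

from eumap import synthdata as sd
from eumap.errors import ConfigurationError, SpacingError
from eumap.separability import GaussianClassSummary, jm_distance


def tiny_truth(**kw):
    t = sd.default_truth(seed=42, shape=kw.pop("shape", (40, 40)))
    for k, v in kw.items():
        setattr(t, k, v)
    return t


class TestSpectralModel:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.ClassSpectralModel(1, np.zeros((3, 8)), -np.ones((3, 8)))

    def test_asymmetric_correlation_rejected(self):
        c = np.eye(8)
        c[0, 1] = 0.5
        with pytest.raises(ConfigurationError):
            sd.ClassSpectralModel(1, np.zeros((3, 8)), np.ones((3, 8)), corr=c)


class TestGenerateScene:
    def test_zero_variance_gives_constant_raster(self):
        t = tiny_truth()
        t.class_params = {1: sd.ClassSpectralModel(
            1, np.full((3, 8), 0.4), np.zeros((3, 8)))}
        scene, _ = sd.generate_scene(t, t.dates[0])
        assert np.all(scene.data == 0.4)

    def test_empirical_means_match_configuration(self):
        # law-of-large-numbers check: ~1e4 px per class on a 2-class mosaic
        t = tiny_truth(shape=(144, 144))
        t.class_params = {
            1: sd.ClassSpectralModel(1, np.full((3, 8), 0.2), np.full((3, 8), 0.05)),
            2: sd.ClassSpectralModel(2, np.full((3, 8), 0.6), np.full((3, 8), 0.05)),
        }
        scene, labels = sd.generate_scene(t, t.dates[0])
        for cid, mu in [(1, 0.2), (2, 0.6)]:
            vals = scene.data[0][labels.data == cid]
            assert len(vals) > 5000
            assert abs(vals.mean() - mu) < 3 * 0.05 / np.sqrt(len(vals))

    def test_deterministic_under_seed(self, truth):
        a, la = sd.generate_scene(truth, "2021-06-28")
        b, lb = sd.generate_scene(truth, "2021-06-28")
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(la.data, lb.data)

    def test_dates_differ(self, truth):
        a, _ = sd.generate_scene(truth, "2021-05-09")
        b, _ = sd.generate_scene(truth, "2021-09-09")
        assert not np.array_equal(a.data, b.data)

    def test_unknown_date_rejected(self, truth):
        with pytest.raises(ConfigurationError):
            sd.generate_scene(truth, "2020-01-01")

    def test_band_schema(self, sept_scene):
        assert sept_scene.band_names == sd.BAND_NAMES
        assert sept_scene.n_bands == 8

    def test_configured_vs_empirical_jm_agree(self, truth, sept_scene, labels):
        # closed-form J-M of the configured Gaussians vs empirical J-M from
        # generated pixels, single band, n >= 1e3 per class
        for band in ("B4", "B6"):
            bi = sd.BAND_NAMES.index(band)
            summaries = {}
            for cid in (2, 5):
                vals = sept_scene.data[bi][labels.data == cid][:4000, None]
                assert len(vals) >= 1000
                summaries[cid] = GaussianClassSummary.from_samples(vals, (band,))
            emp = jm_distance(summaries[2], summaries[5])
            cfg = sd.configured_jm(truth, "2021-09-09", 2, 5, (band,))
            assert abs(emp - cfg) < 0.05


class TestSamplePoints:
    def test_counts_and_spacing(self, samples):
        from scipy.spatial.distance import pdist

        assert len(samples) == sum(sd.FIELD_SAMPLE_COUNTS.values()) == 208
        assert pdist(samples[["x", "y"]].to_numpy()).min() >= 20.0

    @pytest.mark.parametrize("n,expected", [(39, (29, 10)), (28, (21, 7)),
                                            (40, (30, 10)), (4, (3, 1))])
    def test_three_to_one_split_rule(self, n, expected):
        assert sd._train_test_counts(n) == expected

    def test_partition_sizes(self, samples):
        for cid, n in sd.FIELD_SAMPLE_COUNTS.items():
            sub = samples[samples["class_id"] == cid]
            n_train, n_test = sd._train_test_counts(n)
            assert (sub["partition"] == "train").sum() == n_train
            assert (sub["partition"] == "test").sum() == n_test

    def test_single_pixel_class_zero_spacing(self, grid):
        from eumap.raster import Raster

        arr = np.zeros((5, 5), dtype=np.uint8)
        arr[2, 3] = 1
        pts = sd.sample_points(Raster(arr, grid), {1: 1}, 0.0, seed=1)
        x, y = grid.xy(2, 3)
        assert pts.iloc[0]["x"] == x and pts.iloc[0]["y"] == y

    def test_infeasible_spacing_names_class(self, grid):
        from eumap.raster import Raster

        arr = np.full((3, 3), 5, dtype=np.uint8)
        with pytest.raises(SpacingError, match="eucommia"):
            sd.sample_points(Raster(arr, grid), {5: 9}, 1000.0, seed=1)

    def test_deterministic(self, labels):
        a = sd.sample_points(labels, {5: 20}, 20.0, seed=9)
        b = sd.sample_points(labels, {5: 20}, 20.0, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestClimate:
    def test_zero_noise_is_exact_sinusoid(self):
        t = tiny_truth()
        t.climate_params["sol"] = sd.ClimateVariableParams(500.0, 0.0, floor=0.0)
        t.climate_params["temp"] = sd.ClimateVariableParams(14.0, 13.0)
        t.climate_params["precip"] = sd.ClimateVariableParams(57.5, 0.0, floor=0.0)
        c = sd.generate_climate(t)
        assert np.all(c.sol == 500.0)

    def test_monthly_mean_recovers_configuration(self):
        t = tiny_truth(shape=(100, 100))
        t.climate_params["temp"] = sd.ClimateVariableParams(
            13.0, 13.0, peak_month=7, noise_sd=0.5)
        c = sd.generate_climate(t)
        july = c.temp[6]
        assert abs(july.mean() - 26.0) < 0.05

    def test_nonnegative_sol_and_precip(self, truth):
        c = sd.generate_climate(truth)
        assert c.sol.min() >= 0 and c.precip.min() >= 0
        assert c.sol.shape == (12, *truth.shape)

    def test_sol_amplitude_exceeding_mean_rejected(self):
        t = tiny_truth()
        t.climate_params["sol"] = sd.ClimateVariableParams(100.0, 200.0, floor=0.0)
        with pytest.raises(ConfigurationError):
            sd.generate_climate(t)

    def test_deterministic(self, truth):
        a = sd.generate_climate(truth)
        b = sd.generate_climate(truth)
        np.testing.assert_array_equal(a.precip, b.precip)

    def test_bad_month_rejected(self, truth):
        with pytest.raises(ConfigurationError):
            sd.generate_climate(truth, months=[0, 13])


class TestSdmInputs:
    def test_driver_shift_in_occurrences(self, truth):
        occ, _, _ = sd.generate_sdm_inputs(truth, 60, 2000)
        assert occ.presence["BIO17"].mean() > occ.background["BIO17"].mean()

    def test_null_model_no_shift(self):
        t = tiny_truth()
        t.sdm = sd.SdmParams(shape=(60, 60), coefficients={}, intercept=0.0)
        occ, _, _ = sd.generate_sdm_inputs(t, 200, 2000)
        for v in ("BIO17", "BIO4"):
            pooled = np.concatenate([occ.presence[v], occ.background[v]])
            assert abs(occ.presence[v].mean() - occ.background[v].mean()) \
                < 4 * pooled.std() / np.sqrt(200)

    def test_true_surface_scores_occurrences_highly(self, truth):
        from eumap.sdm import roc_auc

        occ, _, true_p = sd.generate_sdm_inputs(truth, 60, 2000)
        sp = true_p.data[true_p.grid.index(occ.presence.x, occ.presence.y)]
        sb = true_p.data[true_p.grid.index(occ.background.x, occ.background.y)]
        assert roc_auc(sp, sb) > 0.9

    def test_layer_schema_and_determinism(self, truth):
        a, ba, _ = sd.generate_sdm_inputs(truth, 20, 100)
        b, bb, _ = sd.generate_sdm_inputs(truth, 20, 100)
        assert ba.band_names == sd.BIO_NAMES and ba.n_bands == 19
        pd.testing.assert_frame_equal(a.presence, b.presence)

    def test_too_few_occurrences_rejected(self, truth):
        with pytest.raises(ConfigurationError):
            sd.generate_sdm_inputs(truth, 5, 100)

    def test_unknown_driver_rejected(self):
        t = tiny_truth()
        t.sdm = sd.SdmParams(coefficients={"BIO99": 1.0})
        with pytest.raises(ConfigurationError):
            sd.generate_sdm_inputs(t, 20, 100)


def test_label_mosaic_covers_all_classes(labels):
    assert set(np.unique(labels.data)) == set(sd.CLASS_NAMES)
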