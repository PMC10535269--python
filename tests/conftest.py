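"""Shared fixtures: one default synthetic study area, reused across modules."""

import numpy as np
import pytest

from eumap import synthdata as sd
from eumap.raster import GridSpec, Raster


@pytest.fixture(scope="session")
def truth():
    return sd.default_truth(seed=0)


@pytest.fixture(scope="session")
def labels(truth):
    return sd.make_label_raster(truth)


@pytest.fixture(scope="session")
def sept_scene(truth):
    scene, _ = sd.generate_scene(truth, "2021-09-09")
    return scene


@pytest.fixture(scope="session")
def samples(labels):
    return sd.sample_points(labels, sd.FIELD_SAMPLE_COUNTS, 20.0, seed=0)


@pytest.fixture()
def grid():
    return GridSpec(0.0, 16000.0, 16.0)


def make_scene(band_values: dict, grid=None, shape=(4, 4)) -> Raster:
    """Tiny constant scene with the given per-band values."""
    g = grid or GridSpec(0.0, 16000.0, 16.0)
    names = tuple(band_values)
    data = np.stack([np.full(shape, v, dtype=float) for v in band_values.values()])
    return Raster(data, g, band_names=names)
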