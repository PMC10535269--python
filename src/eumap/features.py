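"""Radiometric calibration, vegetation indices, and the band-combination registry.

The registry reproduces the comparison design of the mapping experiment:
three band *combinations* used for separability screening (conventional
bands only / plus red edge / plus red-edge indices) and eight *models*
used in the random-forest comparison, differing in which red-edge bands
(B5, B6) and derived indices (NDVI, NDVI710, NDVI750) participate.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .raster import Raster
from .synthdata import BAND_NAMES

log = logging.getLogger(__name__)

INDEX_NAMES = ("NDVI", "NDVI710", "NDVI750")

#: numerator band of each normalized-difference index (denominator band is B3, red)
_INDEX_NUM_BAND = {"NDVI": "B4", "NDVI710": "B5", "NDVI750": "B6"}


@dataclasses.dataclass(frozen=True)
class CalibrationCoefficients:
    """Per-band radiance gain/bias: L = gain * DN + bias."""

    gain: tuple[float, ...]
    bias: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.gain) != len(self.bias):
            raise ConfigurationError("gain and bias must have one entry per band")
        if any(g <= 0 for g in self.gain):
            raise ConfigurationError("gains must be positive")


@dataclasses.dataclass(frozen=True)
class BandCombination:
    """A named subset of bands plus derived indices used as classifier features."""

    id: str
    bands: tuple[str, ...]
    indices: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = [b for b in self.bands if b not in BAND_NAMES]
        unknown += [i for i in self.indices if i not in INDEX_NAMES]
        if unknown:
            raise ConfigurationError(f"combination {self.id}: unknown feature(s) {unknown}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.bands + self.indices

    @property
    def n_features(self) -> int:
        return len(self.bands) + len(self.indices)


_NO_RE = ("B1", "B2", "B3", "B4", "B7", "B8")
_ALL = BAND_NAMES


def screening_combinations() -> dict[str, BandCombination]:
    """The three separability-screening combinations."""
    return {
        "combination1": BandCombination("combination1", _NO_RE),
        "combination2": BandCombination("combination2", _ALL),
        "combination3": BandCombination("combination3", _ALL, ("NDVI", "NDVI710", "NDVI750")),
    }


def model_registry() -> dict[str, BandCombination]:
    """The eight random-forest comparison models."""
    return {
        "model1": BandCombination("model1", _NO_RE),
        "model2": BandCombination("model2", ("B1", "B2", "B3", "B4", "B5", "B7", "B8")),
        "model3": BandCombination("model3", ("B1", "B2", "B3", "B4", "B6", "B7", "B8")),
        "model4": BandCombination("model4", _ALL),
        "model5": BandCombination("model5", _NO_RE, ("NDVI",)),
        "model6": BandCombination("model6", ("B1", "B2", "B3", "B4", "B5", "B7", "B8"),
                                  ("NDVI", "NDVI710")),
        "model7": BandCombination("model7", ("B1", "B2", "B3", "B4", "B6", "B7", "B8"),
                                  ("NDVI", "NDVI750")),
        "model8": BandCombination("model8", _ALL, ("NDVI", "NDVI710", "NDVI750")),
    }


def registry_to_yaml(registry: Mapping[str, BandCombination]) -> str:
    return yaml.safe_dump({k: {"bands": list(v.bands), "indices": list(v.indices)}
                           for k, v in registry.items()}, sort_keys=True)


def registry_from_yaml(text: str) -> dict[str, BandCombination]:
    raw = yaml.safe_load(text)
    return {k: BandCombination(k, tuple(v["bands"]), tuple(v.get("indices", ())))
            for k, v in raw.items()}


# ---------------------------------------------------------------------------
# operations

def calibrate_radiance(dn_raster: Raster, coeffs: CalibrationCoefficients) -> Raster:
    """Apply the linear sensor calibration L = gain * DN + bias per band.

    Nodata (sentinel or NaN) pixels propagate unchanged.
    """
    data = dn_raster.data.astype(float)
    cube = data if data.ndim == 3 else data[None]
    if cube.shape[0] != len(coeffs.gain):
        raise SchemaError(f"raster has {cube.shape[0]} bands but coefficients cover "
                          f"{len(coeffs.gain)}")
    gain = np.asarray(coeffs.gain, dtype=float)[:, None, None]
    bias = np.asarray(coeffs.bias, dtype=float)[:, None, None]
    out = gain * cube + bias
    if dn_raster.nodata is not None and not (
            isinstance(dn_raster.nodata, float) and np.isnan(dn_raster.nodata)):
        mask = cube == dn_raster.nodata
        out[mask] = dn_raster.nodata
    if dn_raster.data.ndim == 2:
        out = out[0]
    return Raster(out, dn_raster.grid, nodata=dn_raster.nodata,
                  band_names=dn_raster.band_names)


def compute_index(scene: Raster, index_name: str) -> Raster:
    """Normalized-difference index (numerator band minus red) / (sum).

    Zero-denominator pixels become NaN (nodata) and are counted in the run log.
    """
    if index_name not in INDEX_NAMES:
        raise ConfigurationError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    num = scene.band(_INDEX_NUM_BAND[index_name]).astype(float)
    red = scene.band("B3").astype(float)
    denom = num + red
    zero = denom == 0
    n_zero = int(zero.sum())
    if n_zero:
        log.info("compute_index(%s): %d zero-denominator pixel(s) set to nodata",
                 index_name, n_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, (num - red) / np.where(zero, 1.0, denom))
    return Raster(out, scene.grid, nodata=np.nan)


def scene_features(scene: Raster, combo: BandCombination) -> Raster:
    """Stack the combination's bands and indices into one feature cube."""
    layers = [scene.band(b).astype(float) for b in combo.bands]
    layers += [compute_index(scene, i).data for i in combo.indices]
    return Raster(np.stack(layers), scene.grid, nodata=np.nan,
                  band_names=combo.feature_names)


def build_feature_table(scene: Raster, samples: pd.DataFrame, combo: BandCombination,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract the combination's features at each sample point (nearest pixel).

    Returns ``(table, excluded)``: one row per in-raster sample with columns
    ``sample_id, class, partition, <features...>`` (bands in B-number order,
    then indices), and an exclusion report listing out-of-raster points.
    """
    cube = scene_features(scene, combo)
    h, w = cube.shape
    if len(samples) == 0:
        empty = pd.DataFrame(columns=["sample_id", "class", "partition",
                                      *combo.feature_names])
        return empty, empty.iloc[:0][["sample_id"]].copy()
    rows, cols = cube.grid.index(samples["x"].to_numpy(), samples["y"].to_numpy())
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    excluded = samples.loc[~inside, ["sample_id", "x", "y"]].copy()
    if len(excluded):
        excluded["reason"] = "outside raster extent"
        log.warning("build_feature_table: %d point(s) outside the raster", len(excluded))
    sel = samples.loc[inside]
    feats = cube.data[:, rows[inside], cols[inside]].T
    table = pd.DataFrame(feats, columns=list(combo.feature_names), index=sel.index)
    table.insert(0, "partition", sel["partition"].to_numpy())
    table.insert(0, "class", sel["class_id"].to_numpy())
    table.insert(0, "sample_id", sel["sample_id"].to_numpy())
    return table.reset_index(drop=True), excluded.reset_index(drop=True)


def feature_matrix(table: pd.DataFrame, combo: BandCombination,
                   partition: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from a feature table, optionally restricted to one partition."""
    t = table if partition is None else table[table["partition"] == partition]
    X = t[list(combo.feature_names)].to_numpy(dtype=float)
    y = t["class"].to_numpy()
    return X, y
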