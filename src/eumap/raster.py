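"""Lightweight georeferenced raster container and plain-TIFF I/O.

All rasters in this package live on a single shared grid convention:
row 0 is the northern edge, coordinates refer to pixel centres, and the
geotransform is the triple ``(origin_x, origin_y, pixel_size)`` where
``(origin_x, origin_y)`` is the outer corner of pixel (0, 0) and
``pixel_size`` is in metres (or the grid unit of the declared CRS).

Rasters are written as plain (uncompressed or zlib) TIFF via
:mod:`tifffile`, with georeferencing, nodata, and band names carried in a
JSON sidecar ``<name>.geo.json`` next to the TIFF.  This keeps every
artifact a text-inspectable pair and avoids a hard GDAL dependency.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a north-up, square-pixel raster grid."""

    origin_x: float
    origin_y: float
    pixel_size: float
    crs: str = "EPSG:32649"

    def xy(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates of (row, col) indices."""
        x = self.origin_x + (np.asarray(cols) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(rows) + 0.5) * self.pixel_size
        return x, y

    def index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-pixel (row, col) of map coordinates (no interpolation)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.pixel_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col


@dataclasses.dataclass
class Raster:
    """A single- or multi-band raster: ``data`` is (rows, cols) or (bands, rows, cols)."""

    data: np.ndarray
    grid: GridSpec
    nodata: float | int | None = None
    band_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"raster data must be 2-D or 3-D, got shape {self.data.shape}")
        if self.band_names is not None:
            self.band_names = tuple(self.band_names)
            if len(self.band_names) != self.n_bands:
                raise ValueError("band_names length does not match band count")

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    def band(self, name: str) -> np.ndarray:
        if self.band_names is None:
            raise KeyError("raster has no band names")
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"band {name!r} not in {self.band_names}") from None
        return self.data[i] if self.data.ndim == 3 else self.data

    def valid_mask(self) -> np.ndarray:
        """True where every band is finite and not equal to the nodata sentinel."""
        d = self.data if self.data.ndim == 3 else self.data[None]
        if np.issubdtype(d.dtype, np.floating):
            ok = np.isfinite(d).all(axis=0)
        else:
            ok = np.ones(d.shape[1:], dtype=bool)
        if self.nodata is not None:
            if np.issubdtype(d.dtype, np.floating) and np.isnan(self.nodata):
                pass  # already covered by the finite check
            else:
                ok &= (d != self.nodata).all(axis=0)
        return ok

    def content_hash(self) -> str:
        """Deterministic hash of array content plus geo metadata (not file bytes)."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(
            json.dumps(
                {
                    "grid": dataclasses.asdict(self.grid),
                    "nodata": None if self.nodata is None else float(self.nodata),
                    "band_names": self.band_names,
                    "dtype": str(self.data.dtype),
                    "shape": list(self.data.shape),
                },
                sort_keys=True,
            ).encode()
        )
        return h.hexdigest()


def write_raster(path: str | Path, raster: Raster) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, raster.data, compression="zlib",
                     photometric="minisblack")
    sidecar = {
        "grid": dataclasses.asdict(raster.grid),
        "nodata": None if raster.nodata is None else float(raster.nodata),
        "band_names": list(raster.band_names) if raster.band_names else None,
    }
    path.with_suffix(path.suffix + ".geo.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_raster(path: str | Path) -> Raster:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".geo.json").read_text())
    nodata = meta.get("nodata")
    if nodata is not None and np.issubdtype(data.dtype, np.integer):
        nodata = int(nodata)
    return Raster(
        data=data,
        grid=GridSpec(**meta["grid"]),
        nodata=nodata,
        band_names=tuple(meta["band_names"]) if meta.get("band_names") else None,
    )


def points_to_geojson(x: Sequence[float], y: Sequence[float], properties: Sequence[dict],
                      crs: str) -> dict:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(xi), float(yi)]},
            "properties": dict(p),
        }
        for xi, yi, p in zip(x, y, properties)
    ]
    return {"type": "FeatureCollection", "crs_name": crs, "features": feats}
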