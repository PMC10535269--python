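"""Synthetic study-area generator with known ground truth.

This module fabricates every input the downstream stages consume:

* multi-date 8-band scenes whose band semantics follow the GF-6 WFV
  camera (blue, green, red, NIR, two red-edge bands, violet, yellow),
  drawn per land-cover class from configured Gaussian spectral models
  over a seeded Voronoi patch mosaic;
* labelled sample points honouring a minimum pairwise spacing and a
  3:1 train/test split;
* monthly climate grids (total solar radiation, mean temperature,
  total precipitation) as seasonal sinusoids over a static smoothed
  spatial field plus pixel noise;
* a monthly NDVI series per vegetation type (for the light-use-efficiency
  NPP stage);
* 19 spatially autocorrelated bioclimatic covariate layers and presence /
  background points sampled from a known logistic suitability surface.

Everything is deterministic under ``SyntheticTruth.seed``: regeneration
with the same truth object is byte-identical.

The default spectral configuration encodes the study conditions the
pipeline is meant to exhibit: the target tree species and the other-forest
class are nearly confusable in the conventional bands, and most of their
mean separation sits in the two red-edge bands (largest in the September
scene), so red-edge-bearing band combinations separate and classify the
pair better *by construction*.  The numbers were set once from the
closed-form Jeffries–Matusita distance of the configured Gaussians; see
``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, spatial
from scipy.special import expit

from .errors import ConfigurationError, SpacingError
from .raster import GridSpec, Raster

# ---------------------------------------------------------------------------
# band and class vocabulary

BAND_NAMES = ("B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8")
BAND_ROLES = {
    "B1": "Blue",
    "B2": "Green",
    "B3": "Red",
    "B4": "Near-infrared",
    "B5": "Red Edge 1",
    "B6": "Red Edge 2",
    "B7": "Violet",
    "B8": "Yellow",
}

CLASS_NAMES = {1: "cropland", 2: "other_forest", 3: "urban", 4: "water", 5: "eucommia"}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}
TARGET_CLASS = 5          # the mapped tree species
FOREST_CLASS = 2          # its hardest confuser

#: reference sample counts per class (cropland, other forest, urban, water, target)
FIELD_SAMPLE_COUNTS = {1: 43, 2: 53, 3: 45, 4: 28, 5: 39}

DATES = ("2021-05-09", "2021-06-28", "2021-09-09")


@dataclasses.dataclass
class ClassSpectralModel:
    """Per-date, per-band Gaussian reflectance model of one land-cover class."""

    class_id: int
    means: np.ndarray      # (n_dates, n_bands)
    sigmas: np.ndarray     # (n_dates, n_bands), >= 0
    corr: np.ndarray | None = None  # optional (n_bands, n_bands) inter-band correlation

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.means.shape != self.sigmas.shape:
            raise ConfigurationError("means and sigmas must have identical shape")
        if (self.sigmas < 0).any():
            raise ConfigurationError("standard deviations must be non-negative")
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if not np.allclose(c, c.T):
                raise ConfigurationError("correlation matrix must be symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ConfigurationError("correlation matrix must be PSD")
            if (np.abs(c) > 1 + 1e-12).any():
                raise ConfigurationError("correlations must lie in [-1, 1]")
            self.corr = c


@dataclasses.dataclass
class ClimateVariableParams:
    """Seasonal sinusoid + noise model of one monthly climate variable."""

    mean: float
    amplitude: float
    peak_month: float = 7.0
    noise_sd: float = 0.0
    spatial_sd: float = 0.0
    spatial_kernel_px: float = 8.0
    floor: float | None = None

    def seasonal(self, month: float) -> float:
        return self.mean + self.amplitude * np.cos(2 * np.pi * (month - self.peak_month) / 12.0)


@dataclasses.dataclass
class NdviSeasonParams:
    winter: float
    summer: float
    peak_month: float = 7.0
    noise_sd: float = 0.02


@dataclasses.dataclass
class SdmParams:
    """Configuration of the occurrence-generating suitability surface."""

    shape: tuple[int, int] = (90, 90)
    pixel_size: float = 1000.0          # 1-km bioclim grid
    kernel_px: float = 6.0              # Gaussian-filter width of the covariate fields
    coefficients: dict[str, float] = dataclasses.field(default_factory=lambda: {"BIO17": 5.0})
    intercept: float = -9.0             # pushes presences into the upper tail of the driver


@dataclasses.dataclass
class SyntheticTruth:
    """Full parameterization of the synthetic study area."""

    seed: int
    shape: tuple[int, int]
    pixel_size: float
    dates: tuple[str, ...]
    class_params: dict[int, ClassSpectralModel]
    climate_params: dict[str, ClimateVariableParams]
    ndvi_params: dict[int, NdviSeasonParams]
    sdm: SdmParams
    n_patches: int = 60
    origin: tuple[float, float] = (400000.0, 3800000.0)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.origin[0], self.origin[1], self.pixel_size)

    def date_index(self, date: str) -> int:
        try:
            return self.dates.index(date)
        except ValueError:
            raise ConfigurationError(f"date {date!r} not covered by this truth "
                                     f"(available: {self.dates})") from None


# ---------------------------------------------------------------------------
# default study conditions

# Per-class mean reflectance by date (rows: May, June, September), bands B1..B8.
_MEANS = {
    4: [  # water: dark, flat, darkest in NIR; stable across the season
        [0.060, 0.080, 0.050, 0.020, 0.040, 0.030, 0.050, 0.060],
        [0.058, 0.078, 0.048, 0.020, 0.038, 0.028, 0.048, 0.058],
        [0.060, 0.080, 0.050, 0.020, 0.040, 0.030, 0.050, 0.060],
    ],
    3: [  # urban: bright, spectrally flat
        [0.175, 0.195, 0.215, 0.235, 0.215, 0.225, 0.155, 0.205],
        [0.185, 0.205, 0.225, 0.245, 0.225, 0.235, 0.165, 0.215],
        [0.180, 0.200, 0.220, 0.240, 0.220, 0.230, 0.160, 0.210],
    ],
    1: [  # cropland: green in May (winter crop), young summer crop in June, stubble in September
        [0.075, 0.115, 0.090, 0.280, 0.150, 0.215, 0.062, 0.105],
        [0.080, 0.120, 0.100, 0.260, 0.150, 0.200, 0.065, 0.110],
        [0.100, 0.140, 0.140, 0.300, 0.180, 0.240, 0.080, 0.130],
    ],
    2: [  # other (deciduous) forest
        [0.050, 0.090, 0.060, 0.350, 0.130, 0.240, 0.040, 0.070],
        [0.042, 0.082, 0.048, 0.450, 0.150, 0.300, 0.033, 0.060],
        [0.045, 0.085, 0.050, 0.420, 0.140, 0.280, 0.035, 0.065],
    ],
    5: [  # target tree species: near the forest class except in the red edge,
        #   which carries the dominant share of the pair's mean separation
        [0.056, 0.098, 0.060, 0.328, 0.150, 0.268, 0.044, 0.078],
        [0.047, 0.089, 0.048, 0.432, 0.163, 0.322, 0.037, 0.067],
        [0.053, 0.095, 0.050, 0.390, 0.172, 0.320, 0.041, 0.075],
    ],
}

_BASE_SIGMA = 0.015
_WATER_SIGMA = 0.010
#: red-band spread of closed tree canopies: red absorption saturates, so the
#: within-class variance is much smaller there than in the open classes.
_TREE_RED_SIGMA = 0.004


def _default_class_params(sigma_scale: float = 1.0) -> dict[int, ClassSpectralModel]:
    out: dict[int, ClassSpectralModel] = {}
    for cid, m in _MEANS.items():
        means = np.asarray(m, dtype=float)
        sig = np.full_like(means, _WATER_SIGMA if cid == 4 else _BASE_SIGMA)
        if cid in (2, 5):
            sig[:, 2] = _TREE_RED_SIGMA  # B3
        out[cid] = ClassSpectralModel(cid, means, sig * sigma_scale)
    return out


def _default_climate_params() -> dict[str, ClimateVariableParams]:
    # Temperate monsoon climate: annual mean ~14 degC, ~690 mm rain concentrated in summer.
    return {
        "sol": ClimateVariableParams(480.0, 220.0, peak_month=7, noise_sd=15.0,
                                     spatial_sd=20.0, floor=0.0),
        "temp": ClimateVariableParams(14.0, 13.0, peak_month=7, noise_sd=0.5,
                                      spatial_sd=0.8),
        "precip": ClimateVariableParams(57.5, 50.0, peak_month=7, noise_sd=8.0,
                                        spatial_sd=10.0, floor=0.0),
    }


def _default_ndvi_params() -> dict[int, NdviSeasonParams]:
    return {
        1: NdviSeasonParams(0.25, 0.65),
        2: NdviSeasonParams(0.25, 0.85),
        3: NdviSeasonParams(0.10, 0.18),
        4: NdviSeasonParams(-0.05, -0.05),
        5: NdviSeasonParams(0.28, 0.80),
    }


def default_truth(seed: int = 0, shape: tuple[int, int] = (160, 160),
                  pixel_size: float = 16.0) -> SyntheticTruth:
    """The red-edge study conditions: target vs other forest is hard without B5/B6."""
    return SyntheticTruth(
        seed=seed,
        shape=shape,
        pixel_size=pixel_size,
        dates=DATES,
        class_params=_default_class_params(),
        climate_params=_default_climate_params(),
        ndvi_params=_default_ndvi_params(),
        sdm=SdmParams(),
    )


def well_separated_truth(seed: int = 0, shape: tuple[int, int] = (160, 160),
                         pixel_size: float = 16.0) -> SyntheticTruth:
    """Same spectral geometry with half the within-class spread.

    On the September scene every pairwise 8-band Jeffries-Matusita distance of
    the configured Gaussians exceeds 1.9 (closed form), the condition for the
    full-raster classification-recovery experiment.
    """
    t = default_truth(seed=seed, shape=shape, pixel_size=pixel_size)
    t.class_params = _default_class_params(sigma_scale=0.5)
    return t


# ---------------------------------------------------------------------------
# label mosaic

def make_label_raster(truth: SyntheticTruth) -> Raster:
    """Seeded Voronoi patch mosaic: contiguous polygonal class patches."""
    rng = np.random.default_rng([truth.seed, 101])
    h, w = truth.shape
    if h <= 0 or w <= 0:
        raise ConfigurationError("raster dimensions must be positive")
    n = max(truth.n_patches, len(truth.class_params))
    sites = rng.uniform(0, 1, size=(n, 2)) * np.array([h, w])
    class_ids = np.array(sorted(truth.class_params))
    # round-robin over shuffled sites so every class is present with similar area
    assignment = np.tile(class_ids, n // len(class_ids) + 1)[:n]
    rng.shuffle(assignment)
    rows, cols = np.mgrid[0:h, 0:w]
    px = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    _, nearest = spatial.cKDTree(sites).query(px)
    labels = assignment[nearest].reshape(h, w).astype(np.uint8)
    return Raster(labels, truth.grid, nodata=0)


# ---------------------------------------------------------------------------
# scenes

def generate_scene(truth: SyntheticTruth, date: str) -> tuple[Raster, Raster]:
    """Draw one 8-band scene for ``date``; returns (scene, label_raster).

    Pixel values are drawn per class from the configured per-date Gaussians
    (optionally correlated across bands).  The label mosaic is shared across
    dates; the noise stream is keyed by (seed, date) so scenes differ between
    dates but are byte-identical across calls.
    """
    di = truth.date_index(date)
    labels = make_label_raster(truth)
    present = np.unique(labels.data)
    missing = [int(c) for c in present if int(c) not in truth.class_params]
    if missing:
        raise ConfigurationError(f"no spectral model for class(es) {missing}")
    rng = np.random.default_rng([truth.seed, 202, di])
    h, w = truth.shape
    nb = len(BAND_NAMES)
    cube = np.empty((nb, h, w), dtype=np.float64)
    for cid in sorted(truth.class_params):
        mask = labels.data == cid
        n = int(mask.sum())
        if n == 0:
            continue
        model = truth.class_params[cid]
        mu = model.means[di]
        sd = model.sigmas[di]
        z = rng.standard_normal((n, nb))
        if model.corr is not None:
            # cov = D C D; draw via Cholesky of C then scale
            lo = np.linalg.cholesky(model.corr + 1e-12 * np.eye(nb))
            z = z @ lo.T
        cube[:, mask] = (mu + z * sd).T
    scene = Raster(cube, truth.grid, band_names=BAND_NAMES)
    return scene, labels


# ---------------------------------------------------------------------------
# sample points

def _train_test_counts(n: int) -> tuple[int, int]:
    """3:1 split; the held-out quarter is rounded half-up, train takes the rest."""
    n_test = int(np.floor(n / 4.0 + 0.5))
    return n - n_test, n_test


def sample_points(label_raster: Raster, n_per_class: Mapping[int, int],
                  min_distance: float, seed: int) -> pd.DataFrame:
    """Seeded spatially constrained sample draw with a fixed 3:1 partition.

    All pairwise distances across the full point set respect ``min_distance``.
    Raises :class:`SpacingError` naming the first class whose request cannot be
    met at the requested spacing.
    """
    rng = np.random.default_rng([seed, 303])
    grid = label_raster.grid
    accepted_xy: list[tuple[float, float]] = []
    rows_out: list[dict] = []
    # spatial hash for the pairwise-distance check
    cell = max(min_distance, grid.pixel_size)
    buckets: dict[tuple[int, int], list[int]] = {}

    def ok(x: float, y: float) -> bool:
        if min_distance <= 0 or not accepted_xy:
            return True
        bi, bj = int(x // cell), int(y // cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in buckets.get((bi + di, bj + dj), ()):
                    ax, ay = accepted_xy[k]
                    if (ax - x) ** 2 + (ay - y) ** 2 < min_distance ** 2:
                        return False
        return True

    for cid in sorted(n_per_class):
        want = int(n_per_class[cid])
        rr, cc = np.nonzero(label_raster.data == cid)
        order = rng.permutation(len(rr))
        got = 0
        for k in order:
            if got == want:
                break
            x, y = grid.xy(rr[k], cc[k])
            x, y = float(x), float(y)
            if ok(x, y):
                idx = len(accepted_xy)
                accepted_xy.append((x, y))
                buckets.setdefault((int(x // cell), int(y // cell)), []).append(idx)
                rows_out.append({"x": x, "y": y, "row": int(rr[k]), "col": int(cc[k]),
                                 "class_id": cid,
                                 "class_name": CLASS_NAMES.get(cid, str(cid))})
                got += 1
        if got < want:
            raise SpacingError(
                f"class {CLASS_NAMES.get(cid, cid)}: only {got}/{want} points possible "
                f"at spacing >= {min_distance} m")
    df = pd.DataFrame(rows_out)
    df["partition"] = "train"
    for cid in sorted(n_per_class):
        idx = df.index[df["class_id"] == cid].to_numpy()
        _, n_test = _train_test_counts(len(idx))
        test_idx = rng.permutation(idx)[:n_test]
        df.loc[test_idx, "partition"] = "test"
    df.insert(0, "sample_id", np.arange(len(df)))
    return df


# ---------------------------------------------------------------------------
# climate

@dataclasses.dataclass
class ClimateStack:
    """Co-registered monthly climate grids (month axis first)."""

    months: tuple[int, ...]
    sol: np.ndarray      # MJ m-2 month-1
    temp: np.ndarray     # degC
    precip: np.ndarray   # mm month-1
    grid: GridSpec

    def raster(self, variable: str) -> Raster:
        return Raster(getattr(self, variable), self.grid,
                      band_names=tuple(f"month_{m:02d}" for m in self.months))


def generate_climate(truth: SyntheticTruth, months: Iterable[int] = range(1, 13)) -> ClimateStack:
    months = tuple(int(m) for m in months)
    if any(m < 1 or m > 12 for m in months):
        raise ConfigurationError("months must lie in 1..12")
    p_sol = truth.climate_params["sol"]
    if p_sol.amplitude > p_sol.mean:
        raise ConfigurationError("solar-radiation amplitude exceeds its mean: "
                                 "the seasonal cycle would go negative")
    h, w = truth.shape
    out: dict[str, np.ndarray] = {}
    for vi, (name, p) in enumerate(sorted(truth.climate_params.items())):
        rng = np.random.default_rng([truth.seed, 404, vi])
        # static geography (one smoothed field reused by every month)
        if p.spatial_sd > 0:
            f = ndimage.gaussian_filter(rng.standard_normal((h, w)), p.spatial_kernel_px)
            f = (f - f.mean()) / max(f.std(), 1e-12) * p.spatial_sd
        else:
            rng.standard_normal((h, w))  # keep the stream layout fixed
            f = np.zeros((h, w))
        stack = np.empty((len(months), h, w))
        for mi, m in enumerate(months):
            v = p.seasonal(m) + f + rng.standard_normal((h, w)) * p.noise_sd
            if p.floor is not None:
                v = np.maximum(v, p.floor)
            stack[mi] = v
        out[name] = stack
    return ClimateStack(months=months, sol=out["sol"], temp=out["temp"],
                        precip=out["precip"], grid=truth.grid)


def generate_ndvi_series(truth: SyntheticTruth, label_raster: Raster | None = None,
                         months: Iterable[int] = range(1, 13)) -> Raster:
    """Monthly NDVI stack driven by per-class seasonal curves."""
    months = tuple(int(m) for m in months)
    if label_raster is None:
        label_raster = make_label_raster(truth)
    rng = np.random.default_rng([truth.seed, 505])
    h, w = truth.shape
    stack = np.zeros((len(months), h, w))
    for cid, p in truth.ndvi_params.items():
        mask = label_raster.data == cid
        if not mask.any():
            continue
        n = int(mask.sum())
        for mi, m in enumerate(months):
            seasonal = p.winter + (p.summer - p.winter) * (
                0.5 + 0.5 * np.cos(2 * np.pi * (m - p.peak_month) / 12.0))
            stack[mi, mask] = seasonal + rng.standard_normal(n) * p.noise_sd
    np.clip(stack, -1.0, 1.0, out=stack)
    return Raster(stack, truth.grid,
                  band_names=tuple(f"month_{m:02d}" for m in months))


# ---------------------------------------------------------------------------
# species-distribution inputs

BIO_NAMES = tuple(f"BIO{i}" for i in range(1, 20))

#: loosely realistic (mean, spatial scale) per bioclimatic variable
BIO_PROFILE = {
    "BIO1": (14.0, 1.5), "BIO2": (10.0, 1.0), "BIO3": (30.0, 3.0), "BIO4": (850.0, 60.0),
    "BIO5": (30.0, 1.5), "BIO6": (-2.0, 1.5), "BIO7": (32.0, 2.0), "BIO8": (24.0, 1.5),
    "BIO9": (2.0, 2.0), "BIO10": (26.0, 1.5), "BIO11": (1.0, 1.5), "BIO12": (690.0, 90.0),
    "BIO13": (150.0, 25.0), "BIO14": (8.0, 4.0), "BIO15": (75.0, 8.0), "BIO16": (380.0, 50.0),
    "BIO17": (28.0, 10.0), "BIO18": (350.0, 45.0), "BIO19": (30.0, 10.0),
}


@dataclasses.dataclass
class OccurrenceSet:
    """Presence/background points with extracted covariate vectors."""

    presence: pd.DataFrame      # columns: x, y, BIO1..BIO19
    background: pd.DataFrame    # same schema
    covariate_names: tuple[str, ...] = BIO_NAMES


def generate_sdm_inputs(truth: SyntheticTruth, n_occurrences: int = 60,
                        n_background: int = 2000, seed: int | None = None,
                        ) -> tuple[OccurrenceSet, Raster, Raster]:
    """Covariate stack, occurrence/background points, and the true surface.

    Returns ``(occurrences, bioclim_stack, true_probability)``.  Occurrence
    cells are drawn (without replacement) with probability proportional to a
    logistic function of the configured standardized drivers; the coefficients
    live on ``truth.sdm`` so recovery can be checked downstream.
    """
    if n_occurrences < 10:
        raise ConfigurationError("need at least 10 occurrences for a meaningful fit")
    p = truth.sdm
    for name in p.coefficients:
        if name not in BIO_NAMES:
            raise ConfigurationError(f"unknown suitability driver {name!r}")
    rng = np.random.default_rng([truth.seed if seed is None else seed, 606])
    h, w = p.shape
    grid = GridSpec(truth.origin[0], truth.origin[1], p.pixel_size)
    z_layers: dict[str, np.ndarray] = {}
    cube = np.empty((len(BIO_NAMES), h, w))
    for i, name in enumerate(BIO_NAMES):
        f = ndimage.gaussian_filter(rng.standard_normal((h, w)), p.kernel_px)
        sd = f.std()
        if sd < 1e-12:
            raise ConfigurationError(f"degenerate (constant) covariate {name}")
        z = (f - f.mean()) / sd
        z_layers[name] = z
        mean, scale = BIO_PROFILE[name]
        cube[i] = mean + scale * z
    eta = np.full((h, w), p.intercept, dtype=float)
    for name, wgt in p.coefficients.items():
        eta += wgt * z_layers[name]
    pi = expit(eta)
    n_cells = h * w
    weights = pi.ravel() / pi.sum()
    occ_idx = rng.choice(n_cells, size=n_occurrences, replace=False, p=weights)
    rest = np.setdiff1d(np.arange(n_cells), occ_idx)
    bg_idx = rng.choice(rest, size=min(n_background, len(rest)), replace=False)

    def table(idx: np.ndarray) -> pd.DataFrame:
        rr, cc = np.unravel_index(idx, (h, w))
        x, y = grid.xy(rr, cc)
        d = {"x": x, "y": y}
        for i, name in enumerate(BIO_NAMES):
            d[name] = cube[i, rr, cc]
        return pd.DataFrame(d)

    occ = OccurrenceSet(presence=table(occ_idx), background=table(bg_idx))
    bioclim = Raster(cube, grid, band_names=BIO_NAMES)
    true_p = Raster(pi, grid)
    return occ, bioclim, true_p


# ---------------------------------------------------------------------------
# closed-form separability of the configured models (for tests and reports)

def configured_jm(truth: SyntheticTruth, date: str, class_a: int, class_b: int,
                  bands: Sequence[str] = BAND_NAMES) -> float:
    """Jeffries-Matusita distance implied by the configured (diagonal) Gaussians."""
    di = truth.date_index(date)
    idx = [BAND_NAMES.index(b) for b in bands]
    ma, mb = truth.class_params[class_a], truth.class_params[class_b]
    mu_a, mu_b = ma.means[di, idx], mb.means[di, idx]
    va, vb = ma.sigmas[di, idx] ** 2, mb.sigmas[di, idx] ** 2
    b = (0.125 * (mu_a - mu_b) ** 2 * 2.0 / (va + vb)
         + 0.5 * np.log((va + vb) / (2.0 * np.sqrt(va * vb)))).sum()
    return float(2.0 * (1.0 - np.exp(-b)))
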