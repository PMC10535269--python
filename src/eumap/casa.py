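"""Light-use-efficiency (CASA) net-primary-productivity estimation.

Monthly NPP at pixel x and month t is

    NPP(x,t) = APAR(x,t) * eps(x,t)
    APAR(x,t) = 0.5 * SOL(x,t) * FPAR(x,t)
    eps(x,t)  = Te1(x,t) * Te2(x,t) * We(x,t) * eps_max

with SOL the monthly total solar radiation (MJ m-2 month-1), FPAR the
NDVI-driven fraction of absorbed photosynthetically active radiation,
Te1/Te2 the two temperature-stress terms, We the water stress, and
eps_max the vegetation-type maximum light-use efficiency (g C MJ-1),
so NPP is in g C m-2 month-1.

Functional forms follow the widely used regional implementation of the
model: a linear NDVI/simple-ratio stretch blend for FPAR (clamped to
[0.001, 0.95]), Te1 = 0.8 + 0.02 Topt - 0.0005 Topt^2, the double-logistic
Te2 with ceiling 1.1814, and We = 0.5 + 0.5 EET/PET where EET comes from a
regional evapotranspiration formula fed by Thornthwaite potential
evapotranspiration.  Every stress function is pluggable on
:class:`CasaModel` so alternates can be swapped in.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, EumapError, UndefinedMetricError
from .jenks import assign_classes, jenks_breaks
from .raster import Raster
from .synthdata import ClimateStack

log = logging.getLogger(__name__)

FPAR_MIN, FPAR_MAX = 0.001, 0.95
TE2_CEILING = 1.1814

#: literature maximum light-use efficiencies (g C MJ-1) by vegetation type;
#: configuration defaults, not ground truth.
EPS_MAX_DEFAULTS = {
    "cropland": 0.542,
    "other_forest": 0.692,       # deciduous broadleaf
    "eucommia": 0.692,           # plantation broadleaf tree
    "shrub": 0.429,
    "grassland": 0.542,
    "urban": 0.389,              # global default for sparse/other cover
    "water": 0.389,
    "default": 0.389,
}


@dataclasses.dataclass
class LueParameters:
    """Per-vegetation-type static parameters of the light-use-efficiency model."""

    eps_max: float                     # g C MJ-1
    ndvi_min: float
    ndvi_max: float
    sr_min: float | None = None
    sr_max: float | None = None

    def __post_init__(self) -> None:
        if self.eps_max <= 0:
            raise ConfigurationError("eps_max must be positive")
        if not self.ndvi_min < self.ndvi_max:
            raise ConfigurationError("need ndvi_min < ndvi_max")
        if self.sr_min is None:
            self.sr_min = simple_ratio(self.ndvi_min)
        if self.sr_max is None:
            self.sr_max = simple_ratio(self.ndvi_max)


def simple_ratio(ndvi):
    """SR = (1 + NDVI) / (1 - NDVI), the simple-ratio transform of NDVI."""
    ndvi = np.clip(np.asarray(ndvi, dtype=float), -1.0, 0.997)
    return (1.0 + ndvi) / (1.0 - ndvi)


# ---------------------------------------------------------------------------
# component terms

def fpar(ndvi, params: LueParameters, alpha: float = 0.5) -> np.ndarray:
    """Fraction of absorbed PAR: alpha-blend of the NDVI and SR linear stretches."""
    if params.ndvi_max - params.ndvi_min <= 0:
        raise DegenerateInputError("degenerate NDVI stretch (min == max)")
    ndvi = np.asarray(ndvi, dtype=float)
    f_ndvi = (ndvi - params.ndvi_min) / (params.ndvi_max - params.ndvi_min) \
        * (FPAR_MAX - FPAR_MIN) + FPAR_MIN
    sr = simple_ratio(ndvi)
    f_sr = (sr - params.sr_min) / (params.sr_max - params.sr_min) \
        * (FPAR_MAX - FPAR_MIN) + FPAR_MIN
    out = alpha * f_ndvi + (1.0 - alpha) * f_sr
    return np.clip(out, FPAR_MIN, FPAR_MAX)


def apar(sol, fpar_arr) -> np.ndarray:
    """Absorbed PAR, MJ m-2 month-1: half the incoming radiation is PAR."""
    sol = np.asarray(sol, dtype=float)
    fpar_arr = np.asarray(fpar_arr, dtype=float)
    if sol.shape != fpar_arr.shape:
        raise EumapError(f"shape mismatch: SOL {sol.shape} vs FPAR {fpar_arr.shape}")
    if (sol < 0).any():
        raise EumapError("negative solar radiation input")
    return 0.5 * sol * fpar_arr


def temperature_stress(temp, t_opt) -> tuple[np.ndarray, np.ndarray]:
    """(Te1, Te2): growth-temperature and departure-from-optimum stresses.

    Te1 depends only on the pixel's optimal temperature (the mean temperature
    of its greenest month); Te2 penalizes months whose temperature departs
    from that optimum, with asymmetric cold/heat shoulders and ceiling 1.1814.
    Both are clamped to be non-negative; Te1 is zeroed where the monthly mean
    is at or below -10 degC (no growth).
    """
    temp = np.asarray(temp, dtype=float)
    t_opt = np.broadcast_to(np.asarray(t_opt, dtype=float), temp.shape)
    if not np.isfinite(t_opt).all():
        raise EumapError("non-finite optimal temperature")
    te1 = 0.8 + 0.02 * t_opt - 0.0005 * t_opt ** 2
    te1 = np.where(temp <= -10.0, 0.0, np.maximum(te1, 0.0))
    with np.errstate(over="ignore"):
        te2 = TE2_CEILING / ((1.0 + np.exp(0.2 * (t_opt - 10.0 - temp)))
                             * (1.0 + np.exp(0.3 * (-t_opt - 10.0 + temp))))
    return te1, np.maximum(te2, 0.0)


def thornthwaite_heat_index(temp_monthly: np.ndarray) -> np.ndarray:
    """Annual heat index I = sum_m (max(T_m,0)/5)^1.514 per pixel."""
    t = np.maximum(np.asarray(temp_monthly, dtype=float), 0.0)
    return ((t / 5.0) ** 1.514).sum(axis=0)


def potential_et(temp, heat_index) -> np.ndarray:
    """Thornthwaite monthly potential evapotranspiration Ep0 (mm month-1)."""
    temp = np.asarray(temp, dtype=float)
    heat_index = np.asarray(heat_index, dtype=float)
    a = (6.75e-7 * heat_index ** 3 - 7.71e-5 * heat_index ** 2
         + 1.792e-2 * heat_index + 0.49239)
    with np.errstate(divide="ignore", invalid="ignore"):
        ep0 = 16.0 * (10.0 * np.maximum(temp, 0.0)
                      / np.where(heat_index > 0, heat_index, np.nan)) ** a
    return np.where((temp > 0) & (heat_index > 0), ep0, 0.0)


def water_stress(precip, temp, heat_index) -> np.ndarray:
    """We = 0.5 + 0.5 EET/PET in [0.5, 1]; 0.5 where PET = 0 (logged).

    EET is the regional estimated evapotranspiration
    ``P Rn (P^2 + Rn^2 + P Rn) / ((P + Rn)(P^2 + Rn^2))`` with net radiation
    ``Rn = sqrt(Ep0 P) (0.369 + 0.598 sqrt(Ep0/P))`` and PET the mean of Ep0
    and EET.
    """
    p = np.asarray(precip, dtype=float)
    ep0 = potential_et(temp, heat_index)
    with np.errstate(divide="ignore", invalid="ignore"):
        rn = np.sqrt(ep0 * p) * (0.369 + 0.598 * np.sqrt(np.where(p > 0, ep0 / p, 0.0)))
        eet = p * rn * (p ** 2 + rn ** 2 + p * rn) / ((p + rn) * (p ** 2 + rn ** 2))
        pet = 0.5 * (ep0 + eet)
        we = np.where(pet > 0, 0.5 + 0.5 * eet / pet, 0.5)
    we = np.where(np.isfinite(we), we, 0.5)
    n_dry = int((pet <= 0).sum())
    if n_dry:
        log.info("water_stress: %d pixel-month(s) with PET = 0 set to We = 0.5", n_dry)
    return np.clip(we, 0.5, 1.0)


def npp_from_components(apar_arr, te1, te2, we, eps_max) -> np.ndarray:
    """NPP = APAR * Te1 * Te2 * We * eps_max (g C m-2 month-1)."""
    return np.asarray(apar_arr, dtype=float) * te1 * te2 * we * eps_max


# ---------------------------------------------------------------------------
# model over a vegetation-type map

def auto_configure(ndvi_series: Raster, veg_types: Raster,
                   eps_max_by_type: dict[int, float],
                   percentiles: tuple[float, float] = (5.0, 95.0),
                   ) -> dict[int, LueParameters]:
    """Per-type NDVI stretch bounds from the type's NDVI time-series percentiles."""
    out: dict[int, LueParameters] = {}
    for vt in np.unique(veg_types.data):
        vt = int(vt)
        if veg_types.nodata is not None and vt == veg_types.nodata:
            continue
        vals = ndvi_series.data[:, veg_types.data == vt].ravel()
        vals = vals[np.isfinite(vals)]
        lo, hi = np.percentile(vals, percentiles)
        if hi - lo < 1e-6:
            lo, hi = lo - 0.05, hi + 0.05  # flat cover type (water, bare): widen
        out[vt] = LueParameters(eps_max=eps_max_by_type.get(vt, EPS_MAX_DEFAULTS["default"]),
                                ndvi_min=float(lo), ndvi_max=float(hi))
    return out


@dataclasses.dataclass
class NPPGrid:
    monthly: np.ndarray   # (12, h, w) g C m-2 month-1
    annual: np.ndarray    # (h, w) g C m-2 a-1
    grid: object
    t_opt: np.ndarray
    params: dict[int, LueParameters]

    def annual_raster(self) -> Raster:
        return Raster(self.annual, self.grid, nodata=np.nan)


@dataclasses.dataclass
class CasaModel:
    """Pluggable CASA runner over a vegetation-type map and 12-month inputs."""

    veg_types: Raster
    params: dict[int, LueParameters]
    fpar_fn: object = staticmethod(fpar)
    temperature_fn: object = staticmethod(temperature_stress)
    water_fn: object = staticmethod(water_stress)

    def optimal_temperature(self, ndvi_series: Raster, climate: ClimateStack) -> np.ndarray:
        """Topt = mean temperature of each pixel's maximum-NDVI month."""
        greenest = np.argmax(ndvi_series.data, axis=0)
        return np.take_along_axis(climate.temp, greenest[None], axis=0)[0]

    def run(self, ndvi_series: Raster, climate: ClimateStack) -> NPPGrid:
        if len(climate.months) != 12 or ndvi_series.data.shape[0] != 12:
            raise EumapError("an annual run needs all 12 months of NDVI and climate")
        h, w = self.veg_types.shape
        t_opt = self.optimal_temperature(ndvi_series, climate)
        heat = thornthwaite_heat_index(climate.temp)
        eps_map = np.full((h, w), np.nan)
        fpar_stack = np.empty_like(ndvi_series.data, dtype=float)
        for vt, p in self.params.items():
            m = self.veg_types.data == vt
            if not m.any():
                continue
            eps_map[m] = p.eps_max
            fpar_stack[:, m] = self.fpar_fn(ndvi_series.data[:, m], p)
        if np.isnan(eps_map).any() and (
                self.veg_types.nodata is None
                or (self.veg_types.data[np.isnan(eps_map)] != self.veg_types.nodata).any()):
            raise ConfigurationError("vegetation type(s) present without LUE parameters")
        monthly = np.zeros((12, h, w))
        for mi in range(12):
            te1, te2 = self.temperature_fn(climate.temp[mi], t_opt)
            we = self.water_fn(climate.precip[mi], climate.temp[mi], heat)
            a = apar(climate.sol[mi], fpar_stack[mi])
            monthly[mi] = np.nan_to_num(
                npp_from_components(a, te1, te2, we, eps_map), nan=0.0)
        return NPPGrid(monthly=monthly, annual=monthly.sum(axis=0),
                       grid=self.veg_types.grid, t_opt=t_opt, params=self.params)


# ---------------------------------------------------------------------------
# zoning, aggregation, validation

NPP_GRADE_LABELS = {1: "low", 2: "medium", 3: "high", 4: "very_high"}


def classify_npp(annual: Raster | np.ndarray, n_classes: int = 4,
                 ) -> tuple[Raster, list[float]]:
    """Natural-breaks grading of annual NPP into ascending classes 1..n."""
    arr = annual.data if isinstance(annual, Raster) else np.asarray(annual, dtype=float)
    grid = annual.grid if isinstance(annual, Raster) else None
    breaks = jenks_breaks(arr[np.isfinite(arr)], n_classes)
    grades = np.where(np.isfinite(arr), assign_classes(arr, breaks), 0).astype(np.uint8)
    return Raster(grades, grid, nodata=0), breaks


def total_carbon(annual: Raster | np.ndarray, mask: np.ndarray,
                 pixel_area_m2: float) -> float:
    """Total carbon over the mask in tonnes C per year (1 t = 1e6 g)."""
    arr = annual.data if isinstance(annual, Raster) else np.asarray(annual, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        log.warning("total_carbon: empty mask, total is 0")
        return 0.0
    vals = arr[mask]
    return float(np.nansum(vals) * pixel_area_m2 * 1e-6)


@dataclasses.dataclass
class ValidationResult:
    rmse: float
    r: float
    r2: float
    points: pd.DataFrame   # row, col, x, y, est, ref
    seed: int


def validate(npp_est: Raster, npp_ref: Raster, n_points: int = 30,
             seed: int = 0) -> ValidationResult:
    """Point-sample agreement between an NPP estimate and a reference raster.

    Draws ``n_points`` seeded random valid pixels, then reports
    RMSE = sqrt(mean (est - ref)^2), the Pearson correlation r, and r^2.
    """
    if npp_est.shape != npp_ref.shape:
        raise EumapError("rasters are not co-registered")
    valid = npp_est.valid_mask() & npp_ref.valid_mask()
    idx = np.flatnonzero(valid)
    if len(idx) < n_points:
        raise EumapError(f"only {len(idx)} valid pixels for {n_points} validation points")
    rng = np.random.default_rng([seed, 707])
    pick = rng.choice(idx, size=n_points, replace=False)
    rr, cc = np.unravel_index(pick, npp_est.shape)
    est = (npp_est.data if npp_est.data.ndim == 2 else npp_est.data[0])[rr, cc]
    ref = (npp_ref.data if npp_ref.data.ndim == 2 else npp_ref.data[0])[rr, cc]
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    if est.std() == 0 or ref.std() == 0:
        raise UndefinedMetricError("zero variance in a validation sample")
    r = float(np.corrcoef(est, ref)[0, 1])
    x, y = npp_est.grid.xy(rr, cc) if npp_est.grid else (cc, rr)
    pts = pd.DataFrame({"row": rr, "col": cc, "x": x, "y": y, "est": est, "ref": ref})
    return ValidationResult(rmse=rmse, r=r, r2=r * r, points=pts, seed=seed)
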