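"""Maximum-entropy presence/background species-distribution modelling.

The model is the Gibbs distribution over the background landscape,
``q(x) = exp(lambda . f(x)) / Z``, whose weights maximize the
L1-regularized mean log-likelihood of the presence sample relative to the
background.  Features are the MaxEnt-conventional expansions of each
covariate scaled to [0, 1] over background: linear, quadratic, and hinge
(forward and reverse, at fixed quantile knots).  Fitting is cyclic
coordinate-wise proximal Newton with a soft-threshold step, converging
when a full cycle improves the regularized gain by less than 1e-5
(iteration cap 1000).  Output is reported on the logistic scale
``p = c e^eta / (1 + c e^eta)`` with ``c = exp(H)``, H the entropy of the
fitted Gibbs distribution — the standard link that makes a typical
presence score about 0.5.

Per-variable diagnostics follow the conventional trio: percent
contribution (share of the cumulative training-gain increments credited
to the variable whose weight moved), permutation importance (normalized
training-AUC drop after shuffling one variable), and jackknife gains
(with-only / without each variable).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigurationError, EumapError, SchemaError
from .jenks import jenks_breaks, assign_classes
from .raster import Raster
from .synthdata import OccurrenceSet

log = logging.getLogger(__name__)

DEFAULT_FIXED_BREAKS = (0.16, 0.35, 0.5)
SUITABILITY_LABELS = {1: "non_suitable", 2: "low", 3: "medium", 4: "high"}


@dataclasses.dataclass(frozen=True)
class MaxentConfig:
    feature_classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    hinge_knots: tuple[float, ...] = (0.25, 0.5, 0.75)
    beta: float = 1.0              # regularization multiplier
    max_iter: int = 1000           # full coordinate cycles
    tol: float = 1e-5              # gain-improvement convergence threshold


@dataclasses.dataclass
class FeatureExpander:
    """Covariate -> feature-matrix mapping frozen at fit time (background ranges)."""

    names: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray
    config: MaxentConfig
    feature_vars: tuple[str, ...] = ()   # variable owning each expanded column
    feature_desc: tuple[str, ...] = ()

    @classmethod
    def from_background(cls, background: pd.DataFrame, names, config: MaxentConfig):
        names = tuple(names)
        arr = background[list(names)].to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise EumapError("non-finite covariates in background")
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        ex = cls(names, lo, hi, config)
        fv, fd = [], []
        for name in names:
            if "linear" in config.feature_classes:
                fv.append(name); fd.append(f"{name}:linear")
            if "quadratic" in config.feature_classes:
                fv.append(name); fd.append(f"{name}:quadratic")
            if "hinge" in config.feature_classes:
                for t in config.hinge_knots:
                    fv.append(name); fd.append(f"{name}:hinge_fwd@{t}")
                    fv.append(name); fd.append(f"{name}:hinge_rev@{t}")
        ex.feature_vars = tuple(fv)
        ex.feature_desc = tuple(fd)
        return ex

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        arr = table[list(self.names)].to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise EumapError("non-finite covariate values")
        rng = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        u = np.clip((arr - self.lo) / rng, 0.0, 1.0)
        u[:, self.hi <= self.lo] = 0.0   # constant covariate -> inert feature
        cols = []
        for i in range(len(self.names)):
            ui = u[:, i]
            if "linear" in self.config.feature_classes:
                cols.append(ui)
            if "quadratic" in self.config.feature_classes:
                cols.append(ui ** 2)
            if "hinge" in self.config.feature_classes:
                for t in self.config.hinge_knots:
                    cols.append(np.maximum(0.0, (ui - t) / (1.0 - t)))
                    cols.append(np.maximum(0.0, (t - ui) / t))
        return np.column_stack(cols)


@dataclasses.dataclass
class MaxentModel:
    expander: FeatureExpander
    lam: np.ndarray
    log_z: float                 # log normalizer over the training background
    entropy: float               # entropy of the fitted Gibbs distribution
    gain: float                  # regularized training gain over uniform
    gain_by_var: dict[str, float]
    config: MaxentConfig
    replicate: int = 0

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Linear predictor eta = lambda . f(x)."""
        return self.expander.transform(table) @ self.lam

    def raw(self, table: pd.DataFrame) -> np.ndarray:
        """exp(eta - log Z): sums to 1 over the training background."""
        return np.exp(self.scores(table) - self.log_z)

    def logistic(self, table: pd.DataFrame) -> np.ndarray:
        r = np.exp(self.scores(table) - self.log_z + self.entropy)
        return r / (1.0 + r)


def _soft(z: float, t: float) -> float:
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def fit(occurrences: OccurrenceSet | tuple[pd.DataFrame, pd.DataFrame],
        config: MaxentConfig = MaxentConfig(), replicate: int = 0,
        presence_subset: np.ndarray | None = None) -> MaxentModel:
    """Fit the regularized maximum-entropy model.

    ``presence_subset`` optionally restricts training to an index subset of
    the presence table (used by the bootstrap replicate harness).
    """
    if isinstance(occurrences, OccurrenceSet):
        pres, bg = occurrences.presence, occurrences.background
        names = occurrences.covariate_names
    else:
        pres, bg = occurrences
        names = tuple(c for c in bg.columns if c not in ("x", "y"))
    if presence_subset is not None:
        pres = pres.iloc[presence_subset]
    ex = FeatureExpander.from_background(bg, names, config)
    Fp = ex.transform(pres)
    Fb = ex.transform(bg)
    n_p, d = Fp.shape
    n_b = Fb.shape[0]
    # presence-conditional feature means and the MaxEnt-style penalty scale
    f_bar = Fp.mean(axis=0)
    s = Fp.std(axis=0)
    beta_j = config.beta * np.maximum(s, 0.05) / np.sqrt(n_p)

    lam = np.zeros(d)
    eta_b = np.zeros(n_b)
    log_z = float(np.log(n_b))
    gain_by_var: dict[str, float] = {v: 0.0 for v in ex.names}

    def objective(lam_v, log_z_v):
        return float(f_bar @ lam_v - log_z_v - beta_j @ np.abs(lam_v))

    obj = objective(lam, log_z)   # = -log n_b at start
    obj0 = obj
    for cycle in range(config.max_iter):
        cycle_start = obj
        q = np.exp(eta_b - log_z)
        for j in range(d):
            fj = Fb[:, j]
            e_q = float(q @ fj)
            var_q = float(q @ (fj - e_q) ** 2)
            if var_q < 1e-12:
                continue
            g = f_bar[j] - e_q
            step = _soft(lam[j] + g / var_q, beta_j[j] / var_q) - lam[j]
            if step == 0.0:
                continue
            improved = False
            for _ in range(6):
                new_eta = eta_b + step * fj
                new_log_z = float(logsumexp(new_eta))
                new_lam_j = lam[j] + step
                delta = (f_bar[j] * step - (new_log_z - log_z)
                         - beta_j[j] * (abs(new_lam_j) - abs(lam[j])))
                if delta > 0 or abs(step) < 1e-12:
                    improved = delta > 0
                    break
                step *= 0.5
            if not improved:
                continue
            lam[j] = lam[j] + step
            eta_b = new_eta
            log_z = new_log_z
            q = np.exp(eta_b - log_z)
            obj += delta
            gain_by_var[ex.feature_vars[j]] += max(delta, 0.0)
        if obj - cycle_start < config.tol:
            break
    q = np.exp(eta_b - log_z)
    entropy = float(-(q * (eta_b - log_z)).sum())
    if np.abs(lam).max() > 50:
        log.warning("fit: very large weight(s) (max |lambda| = %.1f); "
                    "possible separation, capped only by regularization",
                    float(np.abs(lam).max()))
    return MaxentModel(expander=ex, lam=lam, log_z=log_z, entropy=entropy,
                       gain=obj - obj0, gain_by_var=gain_by_var,
                       config=config, replicate=replicate)


# ---------------------------------------------------------------------------
# prediction over rasters

def predict_logistic(model: MaxentModel, covariates: Raster) -> Raster:
    """Logistic suitability raster from a covariate stack (nodata propagates)."""
    if covariates.band_names is None:
        raise SchemaError("covariate raster must carry band names")
    missing = [n for n in model.expander.names if n not in covariates.band_names]
    if missing:
        raise SchemaError(f"missing covariate layer(s): {missing}")
    h, w = covariates.shape
    cols = {n: covariates.band(n).ravel() for n in model.expander.names}
    table = pd.DataFrame(cols)
    valid = np.isfinite(table.to_numpy()).all(axis=1)
    out = np.full(h * w, np.nan)
    if valid.any():
        out[valid] = model.logistic(table.loc[valid])
    return Raster(out.reshape(h, w), covariates.grid, nodata=np.nan)


# ---------------------------------------------------------------------------
# evaluation

def roc_auc(presence_scores, background_scores) -> float:
    """Rank-based AUC of presence vs background scores; ties get half credit."""
    sp = np.asarray(presence_scores, dtype=float)
    sb = np.asarray(background_scores, dtype=float)
    if len(sp) == 0:
        raise EumapError("need at least one test presence")
    if np.ptp(np.concatenate([sp, sb])) == 0:
        log.warning("roc_auc: all scores identical, AUC = 0.5")
        return 0.5
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([sp, sb]))
    rp = ranks[:len(sp)].sum()
    return float((rp - len(sp) * (len(sp) + 1) / 2) / (len(sp) * len(sb)))


@dataclasses.dataclass
class ReplicateResult:
    model: MaxentModel
    auc_test: float
    auc_train: float
    n_train: int
    n_test: int


def bootstrap_replicates(occurrences: OccurrenceSet, config: MaxentConfig = MaxentConfig(),
                         n_replicates: int = 10, train_fraction: float = 0.75,
                         seed: int = 0) -> list[ReplicateResult]:
    """Repeated random 75/25 presence splits, one fitted model per replicate."""
    rng = np.random.default_rng([seed, 808])
    n = len(occurrences.presence)
    n_train = max(1, int(round(train_fraction * n)))
    out = []
    for rep in range(n_replicates):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit(occurrences, config=config, replicate=rep, presence_subset=tr)
        s_bg = model.scores(occurrences.background)
        auc_tr = roc_auc(model.scores(occurrences.presence.iloc[tr]), s_bg)
        auc_te = roc_auc(model.scores(occurrences.presence.iloc[te]), s_bg) \
            if len(te) else float("nan")
        out.append(ReplicateResult(model, auc_te, auc_tr, len(tr), len(te)))
    return out


def variable_importance(model: MaxentModel, occurrences: OccurrenceSet,
                        mode: str = "percent_contribution", seed: int = 0,
                        ) -> pd.DataFrame:
    """Per-variable importance table; percent modes normalize to 100."""
    names = list(model.expander.names)
    if mode == "percent_contribution":
        g = np.array([model.gain_by_var.get(v, 0.0) for v in names])
        total = g.sum()
        pct = g / total * 100.0 if total > 0 else np.full(len(g), 100.0 / len(g))
        return pd.DataFrame({"variable": names, "percent_contribution": pct}) \
            .sort_values("percent_contribution", ascending=False, ignore_index=True)
    if mode == "permutation":
        if len(names) == 1:
            log.info("permutation importance on a single-variable model is trivially 100")
        rng = np.random.default_rng([seed, 909])
        base = roc_auc(model.scores(occurrences.presence), model.scores(occurrences.background))
        drops = []
        both = pd.concat([occurrences.presence, occurrences.background], ignore_index=True)
        n_p = len(occurrences.presence)
        for v in names:
            shuffled = both.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            s = model.scores(shuffled)
            drops.append(max(0.0, base - roc_auc(s[:n_p], s[n_p:])))
        drops = np.asarray(drops)
        tot = drops.sum()
        pct = drops / tot * 100.0 if tot > 0 else np.zeros(len(drops))
        return pd.DataFrame({"variable": names, "permutation_importance": pct}) \
            .sort_values("permutation_importance", ascending=False, ignore_index=True)
    if mode == "jackknife":
        rows = []
        pres, bg = occurrences.presence, occurrences.background
        for v in names:
            only = (pres[["x", "y", v]], bg[["x", "y", v]])
            rest_cols = ["x", "y"] + [n for n in names if n != v]
            without = (pres[rest_cols], bg[rest_cols])
            rows.append({"variable": v,
                         "gain_with_only": fit(only, config=model.config).gain,
                         "gain_without": fit(without, config=model.config).gain})
        return pd.DataFrame(rows)
    raise EumapError(f"unknown importance mode {mode!r}")


# ---------------------------------------------------------------------------
# zoning and area accounting

def classify_suitability(prob: Raster, method: str = "natural_breaks",
                         fixed_breaks=DEFAULT_FIXED_BREAKS,
                         ) -> tuple[Raster, list[float]]:
    """Four-class suitability zoning of a probability raster.

    ``natural_breaks`` reuses the Fisher-Jenks engine (upper-inclusive
    classes); ``fixed_breaks`` applies half-open intervals
    [0, b1), [b1, b2), [b2, b3), [b3, 1].
    """
    arr = prob.data
    finite = np.isfinite(arr)
    if method == "natural_breaks":
        breaks = jenks_breaks(arr[finite], 4)
        grades = np.where(finite, assign_classes(arr, breaks), 0)
    elif method == "fixed_breaks":
        breaks = list(fixed_breaks)
        grades = np.where(finite,
                          np.searchsorted(np.asarray(breaks), arr, side="right") + 1, 0)
    else:
        raise ConfigurationError(f"unknown zoning method {method!r}")
    return Raster(grades.astype(np.uint8), prob.grid, nodata=0), list(map(float, breaks))


def area_by_class(grades: Raster, resolution_km: float) -> dict[int, float]:
    """Pixel-count areas in km^2: count(class) * resolution^2."""
    out = {}
    for g in np.unique(grades.data):
        if grades.nodata is not None and g == grades.nodata:
            continue
        out[int(g)] = float((grades.data == g).sum()) * resolution_km ** 2
    return out
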