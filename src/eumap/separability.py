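"""Jeffries-Matusita class-separability analysis and time-window selection.

The J-M distance between two classes i, j is ``J = 2 (1 - exp(-B))`` with
B the Bhattacharyya distance.  For a single feature under Gaussian
assumptions,

    B = 1/8 (mu_i - mu_j)^2 * 2 / (s_i^2 + s_j^2)
        + 1/2 ln( (s_i^2 + s_j^2) / (2 s_i s_j) )

and for feature vectors the full multivariate Gaussian form with the
pooled covariance (S_i + S_j)/2 is used.  J lies in [0, 2]; values of at
least 1.8 are conventionally read as excellent separability.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, EumapError, SchemaError
from .synthdata import CLASS_NAMES, FOREST_CLASS, TARGET_CLASS

log = logging.getLogger(__name__)

OPTIMAL_JM = 1.8  # "excellent separability" convention


def bhattacharyya_1d(mu_i: float, sigma_i: float, mu_j: float, sigma_j: float) -> float:
    """Univariate Gaussian Bhattacharyya distance."""
    if sigma_i <= 0 or sigma_j <= 0:
        raise DegenerateInputError("Bhattacharyya distance requires positive variances")
    v = sigma_i ** 2 + sigma_j ** 2
    return (0.125 * (mu_i - mu_j) ** 2 * 2.0 / v
            + 0.5 * math.log(v / (2.0 * sigma_i * sigma_j)))


@dataclasses.dataclass
class GaussianClassSummary:
    """Sample mean/covariance summary of one class over a feature set."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    n: int

    @classmethod
    def from_samples(cls, X: np.ndarray, feature_names: Sequence[str]) -> "GaussianClassSummary":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise DegenerateInputError("need at least 2 samples per class")
        cov = np.cov(X, rowvar=False)
        cov = np.atleast_2d(cov)
        return cls(tuple(feature_names), X.mean(axis=0), cov, X.shape[0])

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Ridge the diagonal by 1e-8 * trace/d (small-sample covariances can be singular)."""
    d = cov.shape[0]
    return cov + np.eye(d) * 1e-8 * (np.trace(cov) / d if np.trace(cov) > 0 else 1.0)


def bhattacharyya(summary_i: GaussianClassSummary, summary_j: GaussianClassSummary,
                  mode: str = "multivariate") -> float:
    """Bhattacharyya distance between two class summaries."""
    if summary_i.feature_names != summary_j.feature_names:
        raise SchemaError("summaries cover different feature sets: "
                          f"{summary_i.feature_names} vs {summary_j.feature_names}")
    if mode == "univariate-mean":
        bs = [bhattacharyya_1d(mi, si, mj, sj)
              for mi, si, mj, sj in zip(summary_i.mean, summary_i.sd,
                                        summary_j.mean, summary_j.sd)]
        return float(np.mean(bs))
    if mode != "multivariate":
        raise EumapError(f"unknown mode {mode!r}")
    ci = _regularize(summary_i.cov)
    cj = _regularize(summary_j.cov)
    cm = 0.5 * (ci + cj)
    d = summary_i.mean - summary_j.mean
    sol = np.linalg.solve(cm, d)
    term_mean = 0.125 * float(d @ sol)
    s, ld_m = np.linalg.slogdet(cm)
    if s <= 0:
        raise DegenerateInputError("pooled covariance is not positive definite")
    _, ld_i = np.linalg.slogdet(ci)
    _, ld_j = np.linalg.slogdet(cj)
    term_cov = 0.5 * (ld_m - 0.5 * (ld_i + ld_j))
    return term_mean + term_cov


def jm_from_b(b: float) -> float:
    return float(2.0 * (1.0 - math.exp(-b)))


def jm_distance(summary_i: GaussianClassSummary, summary_j: GaussianClassSummary,
                mode: str = "multivariate") -> float:
    """Jeffries-Matusita distance in [0, 2] between two class summaries."""
    return jm_from_b(bhattacharyya(summary_i, summary_j, mode=mode))


# ---------------------------------------------------------------------------
# report over the (date x combination x pair) design

def class_summaries(table: pd.DataFrame, feature_names: Sequence[str],
                    ) -> dict[int, GaussianClassSummary]:
    out = {}
    for cid, sub in table.groupby("class"):
        X = sub[list(feature_names)].to_numpy(dtype=float)
        if len(X) >= 2:
            out[int(cid)] = GaussianClassSummary.from_samples(X, feature_names)
    return out


def separability_report(tables: Mapping[str, Mapping[str, pd.DataFrame]],
                        target_class: int = TARGET_CLASS,
                        others: Sequence[int] | None = None,
                        mode: str = "multivariate") -> pd.DataFrame:
    """J-M distances of the target class against every other class.

    ``tables[date][combination_id]`` is a feature table whose non-meta columns
    are that combination's features.  Returns long format with one row per
    (date, combination, pair); pairs missing a class are kept with NaN and a
    reason.  Rows with J >= 1.8 carry ``optimal_flag = True``.
    """
    rows = []
    for date in sorted(tables):
        for combo_id in sorted(tables[date]):
            table = tables[date][combo_id]
            feats = [c for c in table.columns
                     if c not in ("sample_id", "class", "partition")]
            summaries = class_summaries(table, feats)
            present = sorted(summaries)
            other_ids = [c for c in (others if others is not None else
                                     sorted(set(table["class"].unique())))
                         if c != target_class]
            for other in other_ids:
                row = {"date": date, "combination": combo_id,
                       "class_a": target_class, "class_b": int(other),
                       "pair": f"{CLASS_NAMES.get(target_class, target_class)}-"
                               f"{CLASS_NAMES.get(other, other)}"}
                if target_class not in summaries or other not in summaries:
                    row.update(jm=np.nan, optimal_flag=False,
                               note=f"class missing in date {date} (present: {present})")
                else:
                    j = jm_distance(summaries[target_class], summaries[int(other)], mode=mode)
                    row.update(jm=j, optimal_flag=j >= OPTIMAL_JM, note="")
                rows.append(row)
    if not rows:
        raise EumapError("empty separability design")
    return pd.DataFrame(rows)


def select_optimal_window(report: pd.DataFrame,
                          target_pair: tuple[int, int] = (TARGET_CLASS, FOREST_CLASS),
                          combination: str | None = None) -> str:
    """Acquisition date maximizing J-M for the hardest pair (ties: earliest date).

    By default the richest combination present in the report is used, since the
    time window is chosen for the final feature set.
    """
    if report.empty:
        raise EumapError("empty separability report")
    a, b = target_pair
    sub = report[((report["class_a"] == a) & (report["class_b"] == b))
                 | ((report["class_a"] == b) & (report["class_b"] == a))]
    if combination is None:
        combination = sorted(sub["combination"].unique())[-1]
    sub = sub[sub["combination"] == combination].dropna(subset=["jm"])
    if sub.empty:
        raise EumapError(f"no J-M entries for pair {target_pair} in {combination!r}")
    best = sub.loc[sub["jm"].idxmax()]
    ties = sub[np.isclose(sub["jm"], best["jm"])]
    date = sorted(ties["date"])[0]
    if len(ties) > 1:
        log.info("select_optimal_window: tie between %s, picking earliest %s",
                 sorted(ties["date"]), date)
    return str(date)


def render_report(report: pd.DataFrame) -> str:
    """Text table mirroring the date x combination layout of the screening design."""
    wide = report.pivot_table(index=["date", "pair"], columns="combination",
                              values="jm", aggfunc="first")
    return wide.round(3).to_string()
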