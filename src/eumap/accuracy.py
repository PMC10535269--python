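"""Confusion-matrix accuracy assessment (count- and area-weighted).

Layout convention: rows are the *mapped* class, columns the *reference*
class, so row totals give user's accuracy (precision) and column totals
give producer's accuracy (recall).  Each segment may carry a positive
weight S_i (its area); count mode is S_i = 1 for all i, and every ratio
metric is identical between a count matrix and an area matrix with unit
weights.
"""

from __future__ import annotations

import dataclasses
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedMetricError


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (matches how the reported percentages are printed)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class ConfusionMatrix:
    classes: tuple
    counts: np.ndarray  # (k, k): rows mapped, columns reference; S_i-weighted

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise SchemaError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise SchemaError("counts must be non-negative")

    # -- construction -------------------------------------------------------
    @classmethod
    def build(cls, reference: Sequence, mapped: Sequence,
              weights: Sequence[float] | None = None,
              classes: Sequence | None = None) -> "ConfusionMatrix":
        reference = np.asarray(reference)
        mapped = np.asarray(mapped)
        if reference.shape != mapped.shape:
            raise SchemaError("reference and mapped label sequences differ in length")
        if weights is None:
            w = np.ones(len(reference), dtype=float)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != reference.shape:
                raise SchemaError("weights must match the label sequences in length")
            if (w <= 0).any():
                raise SchemaError("segment weights must be positive")
        if classes is None:
            classes = sorted(set(reference.tolist()) | set(mapped.tolist()))
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        k = len(classes)
        counts = np.zeros((k, k))
        for r, m, wi in zip(reference, mapped, w):
            if r not in index or m not in index:
                raise SchemaError(f"label outside the class set: {r!r} / {m!r}")
            counts[index[m], index[r]] += wi
        return cls(classes, counts)

    # -- helpers -------------------------------------------------------------
    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def _idx(self, cls_label) -> int:
        try:
            return self.classes.index(cls_label)
        except ValueError:
            raise SchemaError(f"class {cls_label!r} not in {self.classes}") from None

    # -- metrics -------------------------------------------------------------
    def overall_accuracy(self) -> float:
        """OA in percent: weighted diagonal over the grand total."""
        if self.total <= 0:
            raise UndefinedMetricError("empty confusion matrix")
        return 100.0 * float(np.trace(self.counts)) / self.total

    def producer_accuracy(self, cls_label) -> float:
        """PA (recall) in percent: diagonal over the reference (column) total."""
        j = self._idx(cls_label)
        col = float(self.counts[:, j].sum())
        if col <= 0:
            raise UndefinedMetricError(f"no reference segments for class {cls_label!r}")
        return 100.0 * float(self.counts[j, j]) / col

    def user_accuracy(self, cls_label) -> float:
        """UA (precision) in percent: diagonal over the mapped (row) total."""
        j = self._idx(cls_label)
        row = float(self.counts[j, :].sum())
        if row <= 0:
            raise UndefinedMetricError(f"no mapped segments for class {cls_label!r}")
        return 100.0 * float(self.counts[j, j]) / row

    def f1(self, cls_label) -> float:
        """F1 on the 0-1 scale: harmonic mean of precision and recall."""
        p = self.user_accuracy(cls_label) / 100.0
        r = self.producer_accuracy(cls_label) / 100.0
        if p + r == 0:
            return 0.0  # convention for a class never predicted correctly
        return 2.0 * p * r / (p + r)

    def kappa(self) -> float:
        """Cohen's kappa from the row/column marginals."""
        if self.total <= 0:
            raise UndefinedMetricError("empty confusion matrix")
        p = self.counts / self.total
        p0 = float(np.trace(p))
        pe = float(p.sum(axis=0) @ p.sum(axis=1))
        if np.isclose(pe, 1.0):
            raise UndefinedMetricError("chance agreement is 1 (degenerate single class)")
        return (p0 - pe) / (1.0 - pe)

    # -- serialization -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Printed layout: cells plus totals and UA/PA margins."""
        names = [str(c) for c in self.classes]
        df = pd.DataFrame(self.counts, index=names, columns=names)
        df["Total"] = df.sum(axis=1)
        df["UA (%)"] = [round_half_up(self.user_accuracy(c)) if self.counts[i].sum() > 0
                        else np.nan for i, c in enumerate(self.classes)]
        df["F1"] = [round_half_up(self.f1(c), 2)
                    if self.counts[i].sum() > 0 and self.counts[:, i].sum() > 0 else np.nan
                    for i, c in enumerate(self.classes)]
        totals = self.counts.sum(axis=0)
        pa = [round_half_up(self.producer_accuracy(c)) if totals[i] > 0 else np.nan
              for i, c in enumerate(self.classes)]
        df.loc["Total"] = list(totals) + [self.total, np.nan, np.nan]
        df.loc["PA (%)"] = pa + [np.nan, np.nan, np.nan]
        return df

    def to_json(self) -> str:
        return json.dumps({"classes": list(self.classes),
                           "counts": self.counts.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ConfusionMatrix":
        d = json.loads(text)
        return cls(tuple(d["classes"]), np.asarray(d["counts"]))


# module-level functional aliases matching the operation names
def build(reference, mapped, weights=None, classes=None) -> ConfusionMatrix:
    return ConfusionMatrix.build(reference, mapped, weights=weights, classes=classes)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    return cm.overall_accuracy()


def producer_accuracy(cm: ConfusionMatrix, cls_label) -> float:
    return cm.producer_accuracy(cls_label)


def user_accuracy(cm: ConfusionMatrix, cls_label) -> float:
    return cm.user_accuracy(cls_label)


def f1(cm: ConfusionMatrix, cls_label) -> float:
    return cm.f1(cls_label)


def kappa(cm: ConfusionMatrix) -> float:
    return cm.kappa()
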