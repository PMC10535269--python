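"""Exact Fisher-Jenks natural-breaks classification.

Dynamic program minimizing the within-class sum of squared deviations of a
1-D sample split into k ordered classes.  Exact (O(k n^2)) for modest n;
above ``max_exact`` values the breaks are computed on a deterministic
evenly-spaced order-statistic subsample and then applied to the full data.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError


def _ssd_matrix_terms(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])
    return c1, c2


def _seg_cost(c1: np.ndarray, c2: np.ndarray, i: int, j: int) -> float:
    """SSD of sorted values v[i..j] inclusive."""
    n = j - i + 1
    s = c1[j + 1] - c1[i]
    return (c2[j + 1] - c2[i]) - s * s / n


def jenks_breaks(values, k: int, max_exact: int = 3000) -> list[float]:
    """Interior break values (k-1 of them): class g holds v <= breaks[g-1] < next.

    Breaks are reported as the largest member of each lower class (the usual
    natural-breaks convention), so assignment is ``searchsorted(breaks, v)``.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if k < 2:
        raise DegenerateInputError("need k >= 2 classes")
    if np.unique(v).size < k:
        raise DegenerateInputError(f"fewer than {k} distinct finite values")
    v = np.sort(v)
    if len(v) > max_exact:
        idx = np.linspace(0, len(v) - 1, max_exact).round().astype(int)
        v = v[idx]
    n = len(v)
    c1, c2 = _ssd_matrix_terms(v)
    # dp[m][j]: optimal cost of splitting v[0..j] into m+1 classes
    dp = np.empty((k, n))
    back = np.zeros((k, n), dtype=int)
    for j in range(n):
        dp[0, j] = _seg_cost(c1, c2, 0, j)
    for m in range(1, k):
        for j in range(m, n):
            best, arg = np.inf, m
            for i in range(m, j + 1):
                c = dp[m - 1, i - 1] + _seg_cost(c1, c2, i, j)
                if c < best:
                    best, arg = c, i
            dp[m, j] = best
            back[m, j] = arg
    breaks = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = back[m, j]
        breaks.append(float(v[i - 1]))  # last member of the lower class
        j = i - 1
    return breaks[::-1]


def assign_classes(values: np.ndarray, breaks) -> np.ndarray:
    """1-based class index per value: class g iff breaks[g-2] < v <= breaks[g-1]."""
    return np.searchsorted(np.asarray(breaks, dtype=float),
                           np.asarray(values, dtype=float), side="left") + 1
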