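"""Contingency-table statistic kernels shared by `assoc` and `mixture`.

The kernels operate on real-valued 2xC tables so that the identical
formulas serve both the observed-count tests and the noncentrality
computations on *expected* tables (where cells are non-integer).  They
return ``nan`` (and df 0 where applicable) when the statistic is
undefined; callers decide how to report that.
"""

from __future__ import annotations

import math

import numpy as np

ADDITIVE_SCORES = (0.0, 1.0, 2.0)


def drop_empty_columns(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    return table[:, table.sum(axis=0) > 0]


def pearson_stat(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df for a 2xC table.

    Empty (all-zero) columns are dropped and df reduced accordingly;
    no continuity correction.
    """
    t = drop_empty_columns(table)
    if t.shape[1] < 2 or np.any(t.sum(axis=1) <= 0):
        return math.nan, 0
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows * cols / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, t.shape[1] - 1


def trend_z(table, scores=ADDITIVE_SCORES) -> float:
    """Signed Cochran-Armitage trend (score) statistic; row 0 is the index group.

    Uses the score-test variance (total-n denominator, no finite-sample
    correction), which makes Z^2 identical to the score test of the
    additive term in a logistic regression of row membership.
    """
    t = np.asarray(table, dtype=float)
    s = np.asarray(scores, dtype=float)
    n = t.sum()
    r = t[0].sum()
    if not 0.0 < r < n:
        return math.nan
    c = t.sum(axis=0)
    num = n * float(s @ t[0]) - r * float(s @ c)
    var_core = r * (n - r) * (n * float((s * s) @ c) - float(s @ c) ** 2)
    if var_core <= 0.0:
        return math.nan
    return num * math.sqrt(n / var_core)


def two_proportion_z(table) -> float:
    """Pooled-variance two-sample z for the column-1 proportion of a 2x2 table.

    No continuity correction, so z^2 equals the 2x2 Pearson statistic
    exactly.
    """
    t = np.asarray(table, dtype=float)
    n1, n2 = t.sum(axis=1)
    if n1 <= 0 or n2 <= 0:
        return math.nan
    pooled = (t[0, 1] + t[1, 1]) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return math.nan
    diff = t[0, 1] / n1 - t[1, 1] / n2
    return diff / math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
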