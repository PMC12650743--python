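"""Shared statistical kernel: equal-variance t-test and fixed-rank BH.

The entire workflow — gene-level baselines and pair-level ratio tests —
uses one statistic: the two-tailed, two-sample equal-variance (pooled
Student) t-test.  Multiple testing uses the Benjamini–Hochberg step-up with
an explicit family size ``m`` that may exceed the number of p-values
actually tested (the "fixed rank" convention: all candidate features count
toward the family even when a subset is reported).

Degenerate inputs follow a fixed convention so constant ratio vectors never
crash a batch scan: zero pooled variance with equal means gives t = 0,
p = 1; zero pooled variance with unequal means gives p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CASE, CONTROL, DataError, SampleDesign
from .normalize import NormMatrix

__all__ = [
    "TestResult",
    "t_equal_var",
    "t_equal_var_rows",
    "bh_adjust",
    "group_test_matrix",
]


@dataclass
class TestResult:
    t: float
    p: float
    df: int
    n1: int
    n2: int


def t_equal_var(x, y) -> TestResult:
    """Two-tailed, two-sample equal-variance t-test.

    Pooled variance sp² = [(n1−1)s1² + (n2−1)s2²] / (n1+n2−2);
    t = (mean(x) − mean(y)) / sqrt(sp²(1/n1 + 1/n2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("each group needs at least 2 observations")
    t, p = t_equal_var_rows(x[None, :], y[None, :])
    return TestResult(
        t=float(t[0]), p=float(p[0]), df=x.size + y.size - 2,
        n1=x.size, n2=y.size,
    )


def t_equal_var_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled t-test over the rows of two matrices.

    ``x`` is (n_features, n1), ``y`` is (n_features, n2).  Returns arrays of
    t statistics and two-tailed p-values, applying the degenerate
    zero-variance convention row-wise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    m1 = x.mean(axis=1)
    m2 = y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    p = np.empty_like(t)
    degenerate = sp2 == 0
    ok = ~degenerate
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df)
    # sp2 == 0: identical-constant rows -> no evidence; distinct constants
    # -> infinitely strong evidence
    eq = degenerate & (diff == 0)
    ne = degenerate & (diff != 0)
    t[eq] = 0.0
    p[eq] = 1.0
    t[ne] = np.sign(diff[ne]) * np.inf
    p[ne] = 0.0
    return t, p


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with explicit family size.

    ``q(i) = min(1, min_{j ≥ i} m · p(j) / j)`` over p sorted ascending,
    returned in the original order.  ``m`` defaults to ``len(p)`` and must
    not be smaller than it: the family size is the full number of candidate
    tests, never a subset.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise DataError(f"BH family size m={m} smaller than number of tests {n}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(n)
    out[order] = q
    return out


def group_test_matrix(
    values: NormMatrix,
    design: SampleDesign,
    m: int,
    stratify_by_time: bool = False,
) -> pd.DataFrame:
    """Per-gene control-vs-case t-tests on a normalized matrix.

    One pooled test per gene (all time points together), BH-adjusted with
    family size ``m``.  With ``stratify_by_time`` the per-time-point raw
    p-values are reported alongside (columns ``p_<tp>``), unadjusted.

    Returns a DataFrame with columns ``gene_id, t, p, p_adj`` (plus the
    stratified columns), one row per gene in matrix order.
    """
    design.require_group_sizes(2)
    ctrl = design.samples_in_group(CONTROL)
    case = design.samples_in_group(CASE)
    missing = set(ctrl + case) - set(values.sample_ids)
    if missing:
        raise DataError(f"design samples absent from matrix: {sorted(missing)[:5]}")
    x = values.data[ctrl].to_numpy(dtype=float)
    y = values.data[case].to_numpy(dtype=float)
    t, p = t_equal_var_rows(x, y)
    out = pd.DataFrame(
        {"gene_id": values.gene_ids, "t": t, "p": p, "p_adj": bh_adjust(p, m)}
    )
    if stratify_by_time:
        tab = design.table
        for tp in design.time_points:
            sel = tab[tab["time_point"] == tp]
            c_tp = [s for s in sel[sel["group"] == CONTROL]["sample_id"]]
            k_tp = [s for s in sel[sel["group"] == CASE]["sample_id"]]
            if len(c_tp) < 2 or len(k_tp) < 2:
                raise DataError(
                    f"time point {tp!r} lacks 2 samples per group for "
                    "stratified testing"
                )
            _, p_tp = t_equal_var_rows(
                values.data[c_tp].to_numpy(float), values.data[k_tp].to_numpy(float)
            )
            out[f"p_{tp}"] = p_tp
    return out
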