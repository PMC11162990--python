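"""Two-rater intraclass correlation and the ICC reproducibility filter.

Features are computed twice, once per rater's VOI mask; agreement is
quantified with the two-way random-effects, absolute-agreement,
single-measurement ICC — ICC(2,1) in the Shrout–Fleiss taxonomy:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),  k = 2,

from the two-way ANOVA mean squares (rows = subjects, columns = raters).
Features whose ICC falls below the threshold (default 0.80) are excluded
from all downstream modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ICCResult", "icc_two_way_random", "filter_by_icc"]


@dataclass(frozen=True)
class ICCResult:
    feature: str
    icc: float
    retained: bool


def icc_two_way_random(x1, x2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Accepts 1-D arrays (one feature) or 2-D arrays of shape (n, p)
    (column-wise ICCs).  Returns NaN where the data have zero total
    variance (agreement undefined).
    """
    a = np.asarray(x1, float)
    b = np.asarray(x2, float)
    if a.shape != b.shape:
        raise ValueError("rater arrays must have identical shape")
    squeeze = a.ndim == 1
    a, b = np.atleast_2d(a.T).T, np.atleast_2d(b.T).T
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    k = 2
    data = np.stack([a, b], axis=1)            # (n, 2, p)
    grand = data.mean(axis=(0, 1))             # (p,)
    row_m = data.mean(axis=1)                  # (n, p)
    col_m = data.mean(axis=0)                  # (2, p)
    ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_rows = k * ((row_m - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_m - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(ss_total > 0, (msr - mse) / denom, np.nan)
    return float(icc[0]) if squeeze else icc


def filter_by_icc(table_a: pd.DataFrame, table_b: pd.DataFrame,
                  threshold: float = 0.80):
    """Per-feature ICC between two raters' feature tables.

    Returns ``(retained, results)``: the retained feature names and a list
    of :class:`ICCResult` sorted by decreasing ICC.  Non-feature columns
    (``label``, ``cohort``) are ignored.  NaN ICCs (zero-variance features)
    are not retained.
    """
    drop = [c for c in ("label", "cohort") if c in table_a.columns]
    fa = table_a.drop(columns=drop, errors="ignore")
    fb = table_b.drop(columns=[c for c in drop if c in table_b.columns],
                      errors="ignore")
    if list(fa.columns) != list(fb.columns):
        raise ValueError("rater tables must share identical feature columns")
    iccs = icc_two_way_random(fa.to_numpy(), fb.to_numpy())
    results = [ICCResult(c, float(v), bool(np.isfinite(v) and v >= threshold))
               for c, v in zip(fa.columns, iccs)]
    results.sort(key=lambda r: (-(r.icc if np.isfinite(r.icc) else -np.inf),
                                r.feature))
    retained = [r.feature for r in results if r.retained]
    if not retained:
        import warnings
        warnings.warn(f"no features reach ICC threshold {threshold}")
    return retained, results


def icc_lookup(results) -> dict:
    return {r.feature: r.icc for r in results}
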