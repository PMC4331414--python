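"""Cohort statistics: Pearson correlation, paired t-tests, summary tables.

Sample sizes here are small (ten cases by default), so p-values use exact
t-distributions throughout; no multiple-testing correction is applied and
each comparison is reported at alpha = 0.05, matching common practice for
exploratory dosimetric comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TTestResult", "pearson_r", "paired_t_test", "cohort_summary", "ALPHA"]

ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float | None
    degenerate: bool = False


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its exact two-sided p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_t_test(x, y) -> TTestResult:
    """Two-tailed paired Student's t-test on d = x - y (n-1 df).

    Identical pairs give t = 0, p = 1.  Differences that are constant to
    machine precision but non-zero make the statistic undefined; the
    result is flagged degenerate with no p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    scale = max(np.max(np.abs(d)), 1.0)
    if np.ptp(d) < 1e-12 * scale:
        if abs(np.mean(d)) < 1e-12 * scale:
            return TTestResult(0.0, 1.0)
        return TTestResult(math.copysign(math.inf, float(np.mean(d))), None, True)
    t, p = sps.ttest_rel(x, y)
    return TTestResult(float(t), float(p))


_LENGTH_COLS = ["L_true", "L_GRAD", "L_1p4", "L_30pctmax", "L_CT"]


def cohort_summary(table: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Summarise a per-case cohort table.

    Produces mean ± SD for every numeric column, the Pearson correlation
    of each method's length against the ground-truth length, and paired
    t-tests between every gradient-based vs CT-based quantity present (columns named ``<metric>_GRAD`` / ``<metric>_CT``).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 cases to summarise")
    numeric = table.select_dtypes("number")
    summary: dict = {
        "n_cases": int(len(table)),
        "alpha": alpha,
        "columns": {
            col: {"mean": float(numeric[col].mean()), "sd": float(numeric[col].std(ddof=1))}
            for col in numeric.columns
        },
    }
    if "L_true" in numeric:
        corr = {}
        for col in _LENGTH_COLS[1:]:
            if col in numeric:
                r, p = pearson_r(numeric["L_true"], numeric[col])
                corr[col] = {"r": r, "p": p}
        summary["length_correlation_vs_true"] = corr

    plan_metrics = sorted({c[:-5] for c in numeric.columns if c.endswith("_GRAD")
                           and f"{c[:-5]}_CT" in numeric.columns})
    comparisons = {}
    for m in plan_metrics:
        res = paired_t_test(numeric[f"{m}_GRAD"], numeric[f"{m}_CT"])
        comparisons[m] = {
            "mean_GRAD": float(numeric[f"{m}_GRAD"].mean()),
            "sd_GRAD": float(numeric[f"{m}_GRAD"].std(ddof=1)),
            "mean_CT": float(numeric[f"{m}_CT"].mean()),
            "sd_CT": float(numeric[f"{m}_CT"].std(ddof=1)),
            "t": res.t,
            "p": res.p,
            "degenerate": res.degenerate,
            "significant": bool(res.p is not None and res.p < alpha),
        }
    if comparisons:
        summary["paired_comparisons_GRAD_vs_CT"] = comparisons
    return summary
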