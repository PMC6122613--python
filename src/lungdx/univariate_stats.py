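"""Univariate screening of the 110 integration regions: Welch t-tests with
Benjamini-Hochberg correction, fold changes, and the volcano classification.

The two group variances printed for the glutamate region differ by more than
a factor of two, so the unequal-variance (Welch) t-test is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_cohort import Cohort

__all__ = [
    "UnivariateResult",
    "welch_t_test",
    "bh_adjust",
    "univariate_screen",
    "results_to_frame",
    "volcano_table",
]


class StatisticsError(ValueError):
    pass


@dataclass(frozen=True)
class UnivariateResult:
    ir_index: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    fold_change: float
    log2_fold_change: float
    t_statistic: float
    p_value: float
    p_adjusted: float


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatisticsError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatisticsError("samples must be finite")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise StatisticsError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise StatisticsError("p_values must be a non-empty 1-D vector")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise StatisticsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_screen(cohort: Cohort, group_a: str, group_b: str) -> list[UnivariateResult]:
    """Welch test of every IR between two groups, BH-corrected jointly.

    Fold change is ``mean_b / mean_a``; with the conventional ordering
    ``(cancer, inflammation)`` a fold change above 1 means the region is
    elevated in inflammation. Results are returned in IR order.
    """
    if not cohort.normalized:
        raise StatisticsError("univariate_screen requires a normalized cohort")
    matrix = cohort.feature_matrix()
    labels = cohort.labels()
    for g in (group_a, group_b):
        if (labels == g).sum() == 0:
            raise StatisticsError(f"group {g!r} absent from cohort")
    xa = matrix[labels == group_a].to_numpy()
    xb = matrix[labels == group_b].to_numpy()

    n_ir = matrix.shape[1]
    t_stats = np.empty(n_ir)
    p_vals = np.empty(n_ir)
    for j in range(n_ir):
        if xa[:, j].var(ddof=1) == 0 and xb[:, j].var(ddof=1) == 0:
            t_stats[j], p_vals[j] = 0.0, 1.0
        else:
            t_stats[j], p_vals[j] = welch_t_test(xa[:, j], xb[:, j])
    p_adj = bh_adjust(p_vals)

    results = []
    for j in range(n_ir):
        mean_a, mean_b = float(xa[:, j].mean()), float(xb[:, j].mean())
        fc = mean_b / mean_a if mean_a > 0 else float("inf")
        results.append(
            UnivariateResult(
                ir_index=j + 1,
                mean_a=mean_a,
                sd_a=float(xa[:, j].std(ddof=1)),
                mean_b=mean_b,
                sd_b=float(xb[:, j].std(ddof=1)),
                fold_change=fc,
                log2_fold_change=float(np.log2(fc)) if 0 < fc < np.inf else float("nan"),
                t_statistic=float(t_stats[j]),
                p_value=float(p_vals[j]),
                p_adjusted=float(p_adj[j]),
            )
        )
    return results


def results_to_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.ir_index, r.mean_a, r.sd_a, r.mean_b, r.sd_b, r.fold_change,
             r.log2_fold_change, r.t_statistic, r.p_value, r.p_adjusted)
            for r in results
        ],
        columns=["ir_index", "mean_a", "sd_a", "mean_b", "sd_b", "fold_change",
                 "log2_fc", "t", "p", "p_adj"],
    )


def volcano_table(
    results: list[UnivariateResult],
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify each IR for a volcano summary.

    Classes partition the regions: ``significant`` (adjusted p below the
    threshold), ``high_fold_change`` (non-significant but |log2 fold change|
    at or above the threshold), ``negligible`` (the rest).
    """
    rows = []
    for r in results:
        if r.p_adjusted < p_threshold:
            cls = "significant"
        elif np.isfinite(r.log2_fold_change) and abs(r.log2_fold_change) >= lfc_threshold:
            cls = "high_fold_change"
        else:
            cls = "negligible"
        neg_log_p = float(-np.log10(r.p_adjusted)) if r.p_adjusted > 0 else float("inf")
        rows.append((r.ir_index, r.log2_fold_change, neg_log_p, cls))
    return pd.DataFrame(rows, columns=["ir_index", "log2_fc", "neg_log10_p_adj", "class"])
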