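"""Performance metrics, ROC aggregation and per-feature trend annotation.

Balanced accuracy — the mean of sensitivity and specificity — is the
headline metric throughout, since the 22/32 improver / non-improver split
makes raw accuracy misleading. The positive class is always *improver*
(+1), so sensitivity is the rate of correctly identified improvers.

Per-repeat ROC curves (one per repetition of the outer CV, built from that
repeat's pooled out-of-fold decision scores) are aggregated by vertical
averaging on a fixed 101-point false-positive-rate grid with a 95%
normal-approximation band across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .schema import FeatureTable, OutcomeLabels

#: false-positive-rate grid for vertical ROC averaging
FPR_GRID = np.linspace(0.0, 1.0, 101)


def format_percent(fraction: float) -> str:
    """One-decimal percent with half-up rounding (0.6425 -> '64.3%')."""
    q = Decimal(fraction * 100).quantize(Decimal("0.1"),
                                         rounding=ROUND_HALF_UP)
    return f"{q}%"


@dataclass
class PerformanceSummary:
    """Confusion counts and the derived rates for one set of predictions.

    ``accuracy`` is *balanced* accuracy, (sensitivity + specificity) / 2.
    PPV / NPV are NaN (flagged via ``ppv_defined`` / ``npv_defined``) when
    their denominator is zero. ``auc`` is attached separately when decision
    scores are available.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    auc: float = float("nan")

    @property
    def ppv_defined(self) -> bool:
        return not np.isnan(self.ppv)

    @property
    def npv_defined(self) -> bool:
        return not np.isnan(self.npv)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv,
            "npv": self.npv, "auc": self.auc,
        }


def summarize_performance(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> PerformanceSummary:
    """Confusion-matrix rates with improver (+1) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("label lengths differ")
    if not (np.any(y_true == 1) or np.any(y_true == -1)):
        raise ValueError("labels contain neither class")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred != 1)))
    tn = int(np.sum((y_true == -1) & (y_pred != 1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (sens + spec) / 2
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return PerformanceSummary(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                              specificity=spec, accuracy=acc, ppv=ppv,
                              npv=npv)


def roc_points(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (threshold sweep over unique scores, ties crossed
    simultaneously) and trapezoidal AUC."""
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y_true, np.asarray(scores, float), pos_label=1)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


@dataclass
class RocSummary:
    """Vertically averaged ROC across repeats with a 95% band."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mean_auc: float
    n_repeats: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fpr": self.fpr_grid, "mean_tpr": self.mean_tpr,
            "lower95": self.lower, "upper95": self.upper,
        })


def mean_roc(
    curves: Sequence[tuple[np.ndarray, np.ndarray, float]],
    band: str = "normal",
) -> RocSummary:
    """Average per-repeat ROC curves on the fixed FPR grid.

    ``band='normal'``: mean +/- 1.96 x SE across repeats, clipped to
    [0, 1]; ``band='percentile'``: 2.5/97.5 percentiles. Grid endpoints are
    anchored at (0, 0) and (1, 1).
    """
    if len(curves) == 0:
        raise ValueError("no ROC curves to average")
    tprs = []
    for fpr, tpr, _ in curves:
        grid_tpr = np.interp(FPR_GRID, fpr, tpr)
        grid_tpr[0], grid_tpr[-1] = 0.0, 1.0
        tprs.append(grid_tpr)
    T = np.vstack(tprs)
    mean_tpr = T.mean(axis=0)
    n = T.shape[0]
    if band == "percentile":
        lower = np.percentile(T, 2.5, axis=0)
        upper = np.percentile(T, 97.5, axis=0)
    else:
        se = T.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 \
            else np.zeros_like(mean_tpr)
        lower = np.clip(mean_tpr - 1.96 * se, 0.0, 1.0)
        upper = np.clip(mean_tpr + 1.96 * se, 0.0, 1.0)
    mean_auc = float(np.mean([c[2] for c in curves]))
    return RocSummary(FPR_GRID.copy(), mean_tpr, lower, upper, mean_auc, n)


def trend_ttest(
    table: FeatureTable,
    labels: OutcomeLabels,
    features: Sequence[int],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided two-sample t-test per feature, non-improvers vs improvers.

    Sign '+' means the feature is increased in non-improvers relative to
    improvers, '-' decreased; blank when the group means are identical or
    the pooled variance is zero (t undefined, flagged). Annotation only —
    no multiple-testing correction is applied.
    """
    imp = labels.improver
    if imp.sum() < 2 or (~imp).sum() < 2:
        raise ValueError("each class needs >= 2 members for a t-test")
    rows = []
    for j in features:
        a = table.values[~imp, j]  # non-improvers
        b = table.values[imp, j]   # improvers
        diff = a.mean() - b.mean()
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        defined = np.isfinite(t)
        sign = "" if (not defined or diff == 0) else ("+" if diff > 0 else "-")
        rows.append({
            "feature": table.schema.feature_names[j],
            "feature_index": int(j),
            "sign": sign,
            "t": float(t) if defined else float("nan"),
            "p": float(p) if defined else float("nan"),
            "defined": bool(defined),
        })
    return pd.DataFrame(rows)


def performance_table(summaries: dict[str, PerformanceSummary]) -> pd.DataFrame:
    """Long-form metric table, percentages formatted as in reports."""
    rows = []
    for name, s in summaries.items():
        row = {"model": name}
        for metric, value in s.as_dict().items():
            row[metric] = value
        rows.append(row)
    return pd.DataFrame(rows)
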