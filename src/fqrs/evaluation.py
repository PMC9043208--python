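"""Performance metrics: confusion rates, ROC/PR AUC, Cohen's kappa with a
threshold sweep, and Pearson correlation against ordinal labels.

Undefined ratios (e.g. PPV with no positive predictions) are reported as
NaN ("missing"), never silently as 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from fqrs.errors import FQRSError

#: 100 thresholds in [0, 1]; the grid point nearest 0.5 is pinned to 0.5 so
#: the fixed-threshold metric is a special case of the sweep
KAPPA_GRID = np.linspace(0.0, 1.0, 100)
KAPPA_GRID[int(np.argmin(np.abs(KAPPA_GRID - 0.5)))] = 0.5


@dataclass
class MetricReport:
    sens: float
    spec: float
    ppv: float
    roc_auc: float
    pr_auc: float
    kappa: float
    kappa_best_threshold: float
    pearson_r: float | None
    n_pos: int
    n_neg: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), default=float))

    def to_row(self, **extra) -> pd.DataFrame:
        row = {**extra, **asdict(self)}
        return pd.DataFrame([row])


def _check_binary(pred: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    labels = np.asarray(labels)
    if pred.shape != labels.shape:
        raise FQRSError("prediction/label length mismatch")
    return pred.astype(int), labels.astype(int)


def confusion_metrics(binary_pred, labels) -> tuple[float, float, float]:
    """(sensitivity, specificity, PPV); undefined ratios are NaN."""
    pred, y = _check_binary(binary_pred, labels)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return sens, spec, ppv


def roc_pr_auc(scores, labels) -> tuple[float, float]:
    """ROC AUC by the rank (Mann-Whitney) formulation with tie correction;
    PR AUC by interpolation-free step summation."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise FQRSError("ROC/PR require both classes present")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    roc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # PR: walk thresholds from the highest score down
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # collapse ties: only evaluate at the last index of each distinct score
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    pr = float(np.sum((recall - prev_recall) * precision))
    return float(roc), pr


def kappa(binary_pred, labels) -> float:
    """Cohen's kappa; NaN when expected agreement is degenerate."""
    pred, y = _check_binary(binary_pred, labels)
    n = len(y)
    if n == 0:
        return float("nan")
    po = float(np.mean(pred == y))
    p_pred1 = float(np.mean(pred))
    p_y1 = float(np.mean(y))
    pe = p_pred1 * p_y1 + (1 - p_pred1) * (1 - p_y1)
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1 - pe)


def kappa_sweep(scores, labels, thresholds: np.ndarray | None = None) -> tuple[float, float]:
    """Max kappa over a uniform threshold grid (ties -> lowest threshold)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = KAPPA_GRID
    best_k, best_t = -np.inf, thresholds[0]
    for t in thresholds:
        k = kappa((scores >= t).astype(int), y)
        if np.isfinite(k) and k > best_k + 1e-12:
            best_k, best_t = k, t
    if not np.isfinite(best_k):
        return float("nan"), float("nan")
    return float(best_k), float(best_t)


def ordinal_correlation(scores, ordinal_labels) -> tuple[float, float, tuple[float, float]]:
    """Pearson r between continuous scores and ordinal labels, with the
    two-sided p-value and a 95% CI via the Fisher z-transform."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(ordinal_labels, dtype=float)
    if len(scores) < 3:
        raise FQRSError("need at least 3 pairs")
    if labels.std() == 0 or scores.std() == 0:
        raise FQRSError("zero variance input")
    r, p = stats.pearsonr(scores, labels)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(len(scores) - 3)
    ci = (float(np.tanh(z - 1.959963984540054 * se)), float(np.tanh(z + 1.959963984540054 * se)))
    return float(r), float(p), ci


def evaluate_scores(
    scores,
    labels,
    threshold: float = 0.5,
    ordinal_labels=None,
) -> MetricReport:
    """Full metric report for continuous scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    sens, spec, ppv = confusion_metrics(pred, y)
    roc, pr = roc_pr_auc(scores, y)
    best_k, best_t = kappa_sweep(scores, y)
    pearson = None
    if ordinal_labels is not None:
        pearson = ordinal_correlation(scores, ordinal_labels)[0]
    return MetricReport(
        sens=sens,
        spec=spec,
        ppv=ppv,
        roc_auc=roc,
        pr_auc=pr,
        kappa=best_k,
        kappa_best_threshold=best_t,
        pearson_r=pearson,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )
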