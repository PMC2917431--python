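"""ROC/AUC evaluation of topological metrics as predictors of homogeneity.

Each metric is used as a one-dimensional classifier: predict a community
functionally homogeneous when the metric exceeds a threshold, sweep the
threshold over all observed values, and trace the (false positive rate, true
positive rate) curve.  The area under the curve equals the Mann-Whitney
probability that a random positive community outscores a random negative one,
with ties credited 1/2 (diagonal ROC segments).  AUC 0.5 is chance; AUC below
0.5 means the metric predicts homogeneity when *below* a threshold, and is
reported as-is, never sign-flipped.

Per-resolution AUCs are averaged (unweighted) over a log-lambda window —
by default 0 <= log10(lambda) <= 3, excluding the noisy low-resolution end
where only a handful of communities exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class UndefinedAUCError(ValueError):
    """ROC needs at least one positive and one negative label."""


@dataclass
class RocResult:
    metric: str
    log_lambda: float | None
    points: list[tuple[float, float]]  # (FPR, TPR), (0,0) .. (1,1)
    auc: float
    n_pos: int
    n_neg: int


def roc(
    values: Mapping[object, float],
    labels: Mapping[object, bool],
    metric: str = "",
    log_lambda: float | None = None,
) -> RocResult:
    """ROC curve and AUC for one metric at one resolution.

    ``values`` and ``labels`` are keyed by community; communities with missing
    (NaN/None) values are dropped.  AUC is the trapezoidal area, identical to
    the tie-corrected Mann-Whitney statistic.
    """
    keys = [
        k
        for k in values
        if k in labels and values[k] is not None and np.isfinite(values[k])
    ]
    if not keys:
        raise UndefinedAUCError("no communities with finite metric values")
    y = np.array([bool(labels[k]) for k in keys])
    x = np.array([float(values[k]) for k in keys])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"need both classes, got {n_pos} positive / {n_neg} negative"
        )
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, x, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        metric=metric, log_lambda=log_lambda, points=points, auc=auc,
        n_pos=n_pos, n_neg=n_neg,
    )


def mannwhitney_auc(values, labels) -> float:
    """Tie-corrected Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg).

    Independent O(n_pos * n_neg) route used to cross-check the trapezoidal
    computation.
    """
    pos = [float(values[k]) for k in values if labels[k] and np.isfinite(values[k])]
    neg = [float(values[k]) for k in values if not labels[k] and np.isfinite(values[k])]
    if not pos or not neg:
        raise UndefinedAUCError("need both classes")
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def mean_auc(
    results: Iterable[RocResult],
    log_lambda_range: tuple[float, float] = (0.0, 3.0),
) -> tuple[float, dict]:
    """Unweighted mean of per-resolution AUCs inside the log-lambda window.

    Returns (mean, coverage) where coverage reports how many grid points fell
    in range and how many carried a defined AUC.
    """
    lo, hi = log_lambda_range
    in_range = [r for r in results if r.log_lambda is not None and lo <= r.log_lambda <= hi]
    defined = [r for r in in_range if np.isfinite(r.auc)]
    if not defined:
        raise UndefinedAUCError("no defined AUC inside the requested range")
    coverage = {"n_in_range": len(in_range), "n_defined": len(defined)}
    return float(np.mean([r.auc for r in defined])), coverage


def evaluate_metrics(
    metric_table: pd.DataFrame,
    calls,
    measure: str = "G",
    min_size: int = 4,
    log_lambda_range: tuple[float, float] = (0.0, 3.0),
) -> pd.DataFrame:
    """Per-resolution ROC for every metric in a tidy metric table, labelled by
    homogeneity calls under one similarity measure; returns per-metric mean
    AUC over the evaluation window.

    ``metric_table`` columns: log10_lambda, community, size, metric, value
    (as produced by :func:`commscale.topology.sweep_metrics`).
    """
    call_lookup = {
        (c.log_lambda, c.community): c.homogeneous
        for c in calls
        if c.measure == measure and c.size >= min_size
    }
    rows = []
    for metric_name, sub in metric_table.groupby("metric"):
        results = []
        for ll, at_lam in sub.groupby("log10_lambda"):
            values = {}
            labels = {}
            for _, r in at_lam.iterrows():
                key = (ll, r["community"])
                if key in call_lookup and r["size"] >= min_size:
                    values[r["community"]] = r["value"]
                    labels[r["community"]] = call_lookup[key]
            try:
                results.append(roc(values, labels, metric=metric_name, log_lambda=ll))
            except UndefinedAUCError:
                continue
        try:
            mauc, coverage = mean_auc(results, log_lambda_range)
        except UndefinedAUCError:
            continue
        rows.append(
            {
                "metric": metric_name,
                "measure": measure,
                "mean_auc": mauc,
                "n_lambdas": coverage["n_defined"],
            }
        )
    return pd.DataFrame(rows)


def metric_ranking(auc_table: pd.DataFrame) -> pd.DataFrame:
    """Sort the per-metric mean-AUC table, best predictor first (per measure)."""
    return auc_table.sort_values(
        ["measure", "mean_auc"], ascending=[True, False]
    ).reset_index(drop=True)
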