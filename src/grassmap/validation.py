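"""Map-validation metrics.

A normalized accuracy matrix (predicted x expected proportions) with
per-class precision (user's accuracy) and recall (producer's accuracy); a
skill score for probability predictions relative to a constant-prevalence
baseline (R^2 on the log-loss scale); and the inter-annual stability index,
the absolute percentage change of an accuracy metric between consecutive
years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss


@dataclass
class AccuracyMatrix:
    """Normalized confusion matrix (rows = predicted, columns = expected)."""

    labels: list
    cells: np.ndarray  # proportions, (n_labels, n_labels)
    row_totals: np.ndarray = field(init=False)
    col_totals: np.ndarray = field(init=False)
    precision: dict = field(init=False)
    recall: dict = field(init=False)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.float64)
        n = len(self.labels)
        if self.cells.shape != (n, n):
            raise ValueError("cells must be square over the label set")
        if (self.cells < 0).any():
            raise ValueError("cell proportions must be non-negative")
        total = self.cells.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell proportions must sum to 1, got {total}")
        self.row_totals = self.cells.sum(axis=1)
        self.col_totals = self.cells.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.diag(self.cells) / self.row_totals
            rec = np.diag(self.cells) / self.col_totals
        self.precision = dict(zip(self.labels, prec))
        self.recall = dict(zip(self.labels, rec))

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.cells))

    def f1(self, label) -> float:
        p, r = self.precision[label], self.recall[label]
        return 0.0 if (p + r) == 0 else 2.0 * p * r / (p + r)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.cells, index=self.labels, columns=self.labels)
        frame["total"] = self.row_totals
        return frame


def accuracy_matrix(pred, expected) -> AccuracyMatrix:
    """Normalized accuracy matrix from predicted and expected class vectors."""
    pred = np.asarray(pred)
    expected = np.asarray(expected)
    if pred.size == 0 or pred.shape != expected.shape:
        raise ValueError("pred and expected must be equal-length, non-empty")
    labels = sorted(set(pred.tolist()) | set(expected.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    cells = np.zeros((len(labels), len(labels)))
    for p, e in zip(pred, expected):
        cells[index[p], index[e]] += 1
    return AccuracyMatrix(labels=labels, cells=cells / pred.size)


def r2_logloss(
    probabilities, labels, eps: float = 1e-15
) -> float:
    """Log-loss skill relative to a constant-prevalence baseline.

    ``1 - LL_model / LL_baseline`` where the baseline always predicts the
    positive-class prevalence. 1 in the perfect limit, 0 for the baseline
    itself, negative for predictions worse than the baseline.
    """
    p = np.clip(np.asarray(probabilities, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    ll_model = log_loss(y, p, labels=[0, 1])
    baseline = np.full_like(p, y.mean())
    ll_base = log_loss(y, baseline, labels=[0, 1])
    return 1.0 - ll_model / ll_base


@dataclass
class StabilitySeries:
    """Year-pair stability indices of one accuracy metric, in percent."""

    metric: str
    values: dict  # year -> metric value
    index: dict  # (year_prev, year) -> percent change or NaN
    mean_index: float


def stability_index(
    series: dict[int, float],
    metric: str = "",
    denominator: str = "previous",
) -> StabilitySeries:
    """Absolute percentage difference of a metric between consecutive years.

    ``index(t) = |m_t - m_{t-1}| / d * 100`` with ``d`` the previous year's
    value (default) or the pair mean. Values near zero indicate temporally
    stable predictions. Zero denominators leave that pair undefined (NaN).
    """
    if len(series) < 2:
        raise ValueError("need at least two years")
    if denominator not in ("previous", "mean"):
        raise ValueError("denominator must be 'previous' or 'mean'")
    years = sorted(series)
    index: dict = {}
    for prev, cur in zip(years, years[1:]):
        a, b = series[prev], series[cur]
        d = a if denominator == "previous" else (a + b) / 2.0
        index[(prev, cur)] = np.nan if d == 0 else abs(b - a) / d * 100.0
    finite = [v for v in index.values() if np.isfinite(v)]
    mean = float(np.mean(finite)) if finite else np.nan
    return StabilitySeries(
        metric=metric, values=dict(series), index=index, mean_index=mean
    )
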