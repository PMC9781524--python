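"""Binary classifier evaluation: confusion-matrix metrics, AUROC, report.

Six metrics are reported per configuration: accuracy, sensitivity (recall),
specificity, precision, F-score, and AUROC.  AUROC is computed from the full
score ranking as the Mann–Whitney pair statistic
``(#concordant + ½·#tied) / (n₊·n₋)`` — identical to trapezoidal integration
of the ROC curve.  Ratios with zero denominators are reported as NaN with a
warning, never silently as 0.  The positive class defaults to GB (the
majority class); the decision threshold on the sigmoid output is 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "f_score", "auroc")


@dataclass
class EvalReport:
    """Confusion counts, the six metrics, and the ROC point list."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    auroc: float = np.nan
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def metrics(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _to_binary(labels: np.ndarray, positive_class) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = set(np.unique(labels).tolist())
    if len(uniq) > 2:
        raise ValueError(f"labels must be binary, got {sorted(map(str, uniq))}")
    return (labels == positive_class).astype(int)


def confusion_metrics(labels: np.ndarray, predicted: np.ndarray,
                      positive_class="GB") -> EvalReport:
    """Threshold metrics from true and predicted class labels.

    Undefined ratios (zero denominator, e.g. precision with no positive
    predictions) are NaN and trigger a warning.
    """
    y = _to_binary(labels, positive_class)
    yhat = _to_binary(predicted, positive_class)
    if y.size == 0:
        raise ValueError("need at least one case")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fn = int(np.sum((y == 1) & (yhat == 0)))

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                          stacklevel=3)
            return float("nan")
        return num / den

    acc = (tp + tn) / y.size
    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        warnings.warn("F-score undefined; reported as NaN", stacklevel=2)
        f = float("nan")
    else:
        f = 2 * prec * sens / (prec + sens)
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=acc,
                      sensitivity=sens, specificity=spec, precision=prec,
                      f_score=f)


def auroc(labels: np.ndarray, scores: np.ndarray, positive_class="GB") -> float:
    """Area under the ROC curve via the Mann–Whitney pair statistic.

    Equals the probability that a random positive case outranks a random
    negative one, with ties counted half.  Requires both classes present.
    """
    y = _to_binary(labels, positive_class)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(s)                      # mid-ranks handle ties
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve_points(labels: np.ndarray, scores: np.ndarray,
                     positive_class="GB") -> list[tuple[float, float]]:
    """(FPR, TPR) at every distinct score threshold, ends included."""
    y = _to_binary(labels, positive_class)
    s = np.asarray(scores, dtype=np.float64)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int(y.size - y.sum()), 1)
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last point of each tied-score block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    points = [(0.0, 0.0)]
    points += [(fps[i] / n_neg, tps[i] / n_pos)
               for i in np.flatnonzero(distinct)]
    return points


def evaluate_predictions(labels: np.ndarray, scores: np.ndarray,
                         positive_class="GB", threshold: float = 0.5
                         ) -> EvalReport:
    """Full report: threshold metrics at 0.5 plus ranking-based AUROC."""
    labels = np.asarray(labels)
    predicted = np.where(np.asarray(scores) >= threshold, positive_class,
                         "__negative__")
    # map the placeholder to the actual negative label for counting
    neg_labels = [l for l in np.unique(labels) if l != positive_class]
    neg = neg_labels[0] if neg_labels else "__negative__"
    predicted = np.where(predicted == "__negative__", neg, predicted)
    report = confusion_metrics(labels, predicted, positive_class)
    report.auroc = auroc(labels, scores, positive_class)
    report.roc_points = roc_curve_points(labels, scores, positive_class)
    return report


def render_report(reports: dict[str, EvalReport], csv_path=None,
                  image_path=None) -> pd.DataFrame:
    """Configuration × metric matrix; optional CSV and heat-map image.

    Row order follows the insertion order of ``reports``; column order is
    the canonical six-metric order, so repeated renders are stable.
    """
    matrix = pd.DataFrame({name: rep.metrics() for name, rep in reports.items()}
                          ).T[list(METRIC_NAMES)]
    if csv_path is not None:
        matrix.to_csv(csv_path)
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 0.6 * len(matrix) + 1.5))
        im = ax.imshow(matrix.to_numpy(), vmin=0.0, vmax=1.0, cmap="viridis")
        ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=30)
        ax.set_yticks(range(len(matrix.index)), matrix.index)
        for i in range(matrix.shape[0]):
            for j in range(matrix.shape[1]):
                v = matrix.iat[i, j]
                if np.isfinite(v):
                    ax.text(j, i, f"{v:.3f}", ha="center", va="center",
                            color="white" if v < 0.6 else "black", fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return matrix
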