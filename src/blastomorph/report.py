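"""Classification metric suite and machine/human-readable reports.

Metrics per evaluated fold: sensitivity (recall), specificity,
precision, accuracy, F1, AUC, and the false-positive / false-negative
rates (FPR = 1 - specificity, FNR = 1 - sensitivity). AUC is computed
as the normalized Mann-Whitney U rank statistic (ties counted half),
which equals the area under the ROC curve and avoids the edge cases of
trapezoidal integration.

A ratio with a zero denominator (e.g. precision when nothing was
predicted positive) is recorded as 0 with the fold's ``degenerate``
flag set, so downstream averages stay defined.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "METRIC_FIELDS",
    "metrics_from_confusion",
    "auc",
    "metric_set",
    "mean_metrics",
    "write_report",
]

METRIC_FIELDS = ("sensitivity", "specificity", "precision", "accuracy",
                 "f1", "auc", "fpr", "fnr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int],
                         y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must align")
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    auc: float
    fpr: float
    fnr: float
    #: True when any ratio had a zero denominator and was recorded as 0.
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        d = {k: float(getattr(self, k)) for k in METRIC_FIELDS}
        d["degenerate"] = bool(self.degenerate)
        return d


def _ratio(num: float, den: float, flag: list[bool]) -> float:
    if den == 0:
        flag.append(True)
        return 0.0
    return num / den


def metrics_from_confusion(c: ConfusionCounts,
                           auc_value: Optional[float] = None) -> MetricSet:
    """All threshold metrics from a confusion table (AUC supplied or NaN-free 0)."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    flag: list[bool] = []
    sens = _ratio(c.tp, c.tp + c.fn, flag)
    spec = _ratio(c.tn, c.tn + c.fp, flag)
    prec = _ratio(c.tp, c.tp + c.fp, flag)
    acc = (c.tp + c.tn) / c.total
    f1 = _ratio(2 * prec * sens, prec + sens, flag)
    if flag:
        warnings.warn("metric with zero denominator recorded as 0",
                      stacklevel=2)
    return MetricSet(
        sensitivity=sens, specificity=spec, precision=prec, accuracy=acc,
        f1=f1, auc=0.0 if auc_value is None else float(auc_value),
        fpr=1.0 - spec, fnr=1.0 - sens, degenerate=bool(flag),
    )


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the probability that a random positive scores above a
    random negative, ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def metric_set(y_true: Sequence[int], y_pred: Sequence[int],
               scores: Sequence[float]) -> MetricSet:
    """Full metric set for one evaluated fold."""
    c = ConfusionCounts.from_predictions(y_true, y_pred)
    return metrics_from_confusion(c, auc_value=auc(scores, y_true))


def mean_metrics(metrics: Sequence[MetricSet]) -> MetricSet:
    """Field-wise arithmetic mean across folds."""
    if not metrics:
        raise ValueError("cannot average an empty metric list")
    means = {k: float(np.mean([getattr(m, k) for m in metrics]))
             for k in METRIC_FIELDS}
    return MetricSet(**means, degenerate=any(m.degenerate for m in metrics))


def _result_to_dict(result) -> dict:
    return {
        "classifier": {
            "family": result.spec.family,
            "hyperparameters": dict(result.spec.hyperparameters),
            "seed": result.spec.seed,
        },
        "seed": result.seed,
        "k_folds": len(result.per_fold),
        "permuted": result.permuted,
        "fold_assignment": dict(result.fold_assignment),
        "per_fold": [m.as_dict() for m in result.per_fold],
        "averaged": result.averaged.as_dict(),
    }


def write_report(results: Sequence, out_dir: str | Path,
                 figure: bool = False) -> dict[str, Path]:
    """Write cross-validation results as JSON + CSV (+ optional figure).

    The JSON carries full precision and per-fold detail with stable key
    order; the CSV summary rounds to 4 decimals. Output is a function of
    the results alone, so fixed seeds give byte-identical reports.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    payload = {"results": [_result_to_dict(r) for r in results]}
    json_path = out_dir / "results.json"
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    rows = []
    for r in results:
        row = {"classifier": r.spec.family, "permuted": r.permuted}
        row.update({k: round(v, 4) for k, v in r.averaged.as_dict().items()
                    if k != "degenerate"})
        rows.append(row)
    csv_path = out_dir / "summary.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.4f")

    paths = {"json": json_path, "csv": csv_path}
    if figure:
        paths["figure"] = _metric_figure(results, out_dir / "figure.png")
    return paths


def _metric_figure(results, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fams = [r.spec.family for r in results]
    fields = [f for f in METRIC_FIELDS if f not in ("fpr", "fnr")]
    x = np.arange(len(fields))
    width = 0.8 / max(len(results), 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    for i, r in enumerate(results):
        vals = [getattr(r.averaged, f) for f in fields]
        ax.bar(x + i * width, vals, width, label=fams[i])
    ax.set_xticks(x + width * (len(results) - 1) / 2)
    ax.set_xticklabels(fields, rotation=30)
    ax.set_ylim(0, 1)
    ax.set_ylabel("fold-averaged value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
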