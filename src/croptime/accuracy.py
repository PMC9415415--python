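"""Accuracy assessment: confusion matrices, OA/PA/UA, Cohen's kappa, and the
within-season evaluation timeline.

Overall accuracy (OA) is the fraction of correctly classified sampling
units; producer's accuracy (PA) is per-true-class recall and user's accuracy
(UA) per-predicted-class precision.  Cohen's kappa corrects observed
agreement p_o for the agreement p_e expected if predictions were independent
of the truth:

    kappa = (p_o - p_e) / (1 - p_e)

and is qualified with Altman's bands: poor (<= 0.20), regular (0.21-0.40),
moderate (0.41-0.60), good (0.61-0.80), particularly good (0.81-1).
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "AccuracyReport", "confusion",
           "overall_accuracy", "producers_accuracy", "users_accuracy",
           "kappa", "altman_rating", "accuracy_report", "evaluate",
           "timeline_evaluate", "plot_timeline"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table; rows are ground truth, columns predictions."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError("counts must be square and match the class list")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass(frozen=True)
class AccuracyReport:
    overall_accuracy: float                    # percent
    producers_accuracy: dict[str, float]       # percent per class (NaN if undefined)
    users_accuracy: dict[str, float]           # percent per class (NaN if undefined)
    kappa: float
    altman_rating: str
    confusion: ConfusionMatrix
    n: int


def confusion(truth: Sequence, predicted: Sequence,
              vocabulary: Optional[Iterable] = None) -> ConfusionMatrix:
    """Cross-tabulate ground truth against predictions."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lists differ in length")
    if vocabulary is None:
        vocabulary = sorted({*truth, *predicted}, key=str)
    classes = tuple(str(c) for c in vocabulary)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        try:
            counts[index[str(t)], index[str(p)]] += 1
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in vocabulary") from None
    return ConfusionMatrix(classes=classes, counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified sampling units."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def producers_accuracy(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-class recall in percent; NaN where a class has no true samples."""
    row = cm.counts.sum(axis=1)
    diag = np.diag(cm.counts)
    return {c: (100.0 * diag[i] / row[i]) if row[i] > 0 else math.nan
            for i, c in enumerate(cm.classes)}


def users_accuracy(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-class precision in percent; NaN where a class was never predicted."""
    col = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    return {c: (100.0 * diag[i] / col[i]) if col[i] > 0 else math.nan
            for i, c in enumerate(cm.classes)}


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement of the confusion matrix."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / n
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: expected agreement is 1 "
                         "(all mass in a single cell)")
    return (p_o - p_e) / (1.0 - p_e)


#: Altman band upper edges and labels (half-open intervals, upper inclusive).
_ALTMAN_BANDS = ((0.20, "poor"), (0.40, "regular"), (0.60, "moderate"),
                 (0.80, "good"), (1.00, "particularly good"))


def altman_rating(kappa_value: float) -> str:
    """Qualitative Altman rating of a kappa value; negatives rate as poor."""
    if not -1.0 <= kappa_value <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa_value}")
    for upper, label in _ALTMAN_BANDS:
        if kappa_value <= upper:
            return label
    return "particularly good"  # pragma: no cover - kappa == 1 handled above


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """Full OA/PA/UA/kappa report with the Altman rating."""
    k = kappa(cm)
    return AccuracyReport(
        overall_accuracy=overall_accuracy(cm),
        producers_accuracy=producers_accuracy(cm),
        users_accuracy=users_accuracy(cm),
        kappa=k,
        altman_rating=altman_rating(k),
        confusion=cm,
        n=cm.total,
    )


def evaluate(model, table: pd.DataFrame, feature_columns: Sequence[str],
             vocabulary: Optional[Iterable] = None) -> AccuracyReport:
    """Predict a labelled feature table and score it."""
    truth = table["crop_label"].to_numpy()
    pred = model.predict(table[list(feature_columns)])
    if vocabulary is None:
        vocabulary = [str(c) for c in model.classes_]
    return accuracy_report(confusion(truth, pred, vocabulary))


def timeline_evaluate(models: Mapping[str, object], test_dataset: pd.DataFrame,
                      calendar, dates: Sequence[dt.date], soil_line,
                      emergence_threshold: float = 0.005,
                      filter_scope: str = "all",
                      tolerance: Optional[int] = None) -> pd.DataFrame:
    """Score each lag combination's model on each analysis date of a new cycle.

    ``models`` maps combination ids to fitted classifiers trained on the
    previous cycle.  For each requested date and each combination whose lag
    scheme can be matched in ``calendar``, records are assembled from the
    test cycle (no retraining) and scored.  Returns a tidy frame with one row
    per (date, combination) carrying OA, kappa, the Altman rating, per-class
    PA/UA and the record count; dates where a combination is infeasible
    simply contribute no row.
    """
    from .stacking import (assemble_training_table, combination,
                           descriptor_columns, match_scenes)

    rows = []
    for adate in dates:
        for comb_id, model in models.items():
            spec = combination(comb_id, tolerance)
            if match_scenes(calendar.cloud_free, adate, spec) is None:
                continue  # this combination cannot be formed on this date
            table = assemble_training_table(
                test_dataset, calendar, spec, soil_line,
                analysis_dates=[adate],
                emergence_threshold=emergence_threshold,
                filter_scope=filter_scope)
            if table.empty:
                continue
            report = evaluate(model, table, descriptor_columns(spec))
            row = {"date": adate, "combination": spec.id,
                   "n_records": report.n,
                   "overall_accuracy": report.overall_accuracy,
                   "kappa": report.kappa,
                   "altman_rating": report.altman_rating}
            for cls, v in report.producers_accuracy.items():
                row[f"PA_{cls}"] = v
            for cls, v in report.users_accuracy.items():
                row[f"UA_{cls}"] = v
            rows.append(row)
    if not rows:
        warnings.warn("no feasible (date, combination) pairs in the timeline",
                      stacklevel=2)
        return pd.DataFrame(columns=["date", "combination", "n_records",
                                     "overall_accuracy", "kappa",
                                     "altman_rating"])
    return pd.DataFrame(rows).sort_values(["date", "combination"]).reset_index(drop=True)


def plot_timeline(timeline: pd.DataFrame, path=None):
    """Plot OA and kappa against the analysis date, one line per combination."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_oa, ax_k) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    for comb, grp in timeline.groupby("combination"):
        ax_oa.plot(grp["date"], grp["overall_accuracy"], marker="o", label=comb)
        ax_k.plot(grp["date"], grp["kappa"], marker="o", label=comb)
    ax_oa.set_ylabel("Overall accuracy (%)")
    ax_k.set_ylabel("Kappa")
    ax_k.set_xlabel("Analysis date")
    ax_oa.legend(title="Combination")
    fig.autofmt_xdate()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
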