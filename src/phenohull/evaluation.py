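"""Evaluation toolkit: confusion metrics, RMSE, agreement, tests, CV.

Accuracy / precision / recall follow the standard confusion-matrix
definitions with a caller-designated positive class.  Report strings
truncate (not round) to two decimals, so 8/11 = 0.7272... prints as 0.72;
full-precision values are always carried alongside.

Inter-rater agreement is Fleiss kappa for >= 2 raters (Cohen kappa for the
two-rater case), the location test is Welch's unequal-variance t, and the
k-fold harness refits classification intervals on the training folds
before scoring the held-out plants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats import inter_rater

from .planttype import (
    CYLINDER,
    TOWER,
    TypeIntervals,
    classify_plant,
    fit_intervals,
)
from .planttype import CornerRateSample

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "rmse",
    "confusion_from_labels",
    "metrics",
    "fleiss_kappa",
    "cohen_kappa",
    "welch_t_test",
    "kfold_cross_validate",
    "truncate2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts for a designated positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall in [0, 1]; NaN marks an undefined
    metric (zero denominator)."""

    accuracy: float
    precision: float
    recall: float

    def printed(self) -> dict[str, str]:
        """Two-decimal truncated strings as used in report tables."""
        return {
            "accuracy": truncate2(self.accuracy),
            "precision": truncate2(self.precision),
            "recall": truncate2(self.recall),
        }


def truncate2(x: float) -> str:
    """Truncate toward zero to 2 decimals (0.727 -> '0.72')."""
    if math.isnan(x):
        return "nan"
    return f"{math.trunc(x * 100) / 100:.2f}"


def rmse(predicted, truth) -> float:
    """Root mean square error between equal-length vectors."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(np.sqrt(np.mean((predicted - truth) ** 2)))


def confusion_from_labels(
    truth, predicted, positive: str = CYLINDER
) -> ConfusionCounts:
    """Tally binary confusion counts from parallel label lists."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted) or not truth:
        raise ValueError("label lists must be equal-length and nonempty")
    tp = fp = fn = tn = 0
    for t, p in zip(truth, predicted):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall from confusion counts.

    ``accuracy = (TP+TN)/(TP+FP+FN+TN)``, ``precision = TP/(TP+FP)``,
    ``recall = TP/(TP+FN)``.  A zero denominator yields NaN for the
    affected metric rather than an exception.
    """
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (counts.tp + counts.tn) / counts.total
    prec = (
        counts.tp / (counts.tp + counts.fp)
        if counts.tp + counts.fp > 0
        else math.nan
    )
    rec = (
        counts.tp / (counts.tp + counts.fn)
        if counts.tp + counts.fn > 0
        else math.nan
    )
    return MetricsReport(accuracy=acc, precision=prec, recall=rec)


def fleiss_kappa(ratings) -> float:
    """Fleiss kappa for a subjects x raters categorical table.

    Each row holds one subject's labels from every rater (any hashable
    categories).  1.0 means perfect agreement; the statistic is undefined
    (ZeroDivisionError) when every rating in the table is one category.
    """
    table = np.asarray(ratings, dtype=object)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    categories = sorted({x for row in table for x in row}, key=str)
    if len(categories) < 2:
        raise ZeroDivisionError(
            "kappa undefined: a single category across all cells"
        )
    index = {c: j for j, c in enumerate(categories)}
    counts = np.zeros((table.shape[0], len(categories)), dtype=int)
    for i, row in enumerate(table):
        for x in row:
            counts[i, index[x]] += 1
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def cohen_kappa(rater_a, rater_b) -> float:
    """Cohen kappa for two raters' parallel label lists."""
    return float(cohen_kappa_score(list(rater_a), list(rater_b)))


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch unequal-variance two-sided t test: (t, df, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        # degenerate null case: identical constants
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def kfold_cross_validate(
    plant_rate_sets: list[tuple[str, "list[float] | np.ndarray"]],
    k: int = 5,
    seed: int = 0,
    method: str = "minmax",
    positive: str = CYLINDER,
    return_folds: bool = False,
) -> "list[MetricsReport] | tuple[list[MetricsReport], list[np.ndarray]]":
    """Seeded k-fold cross-validation of the interval classifier.

    ``plant_rate_sets`` holds one ``(truth_label, |K'| rates)`` entry per
    plant.  Plants are shuffled once by ``seed`` and cut into k near-equal
    contiguous folds; for each fold, intervals are fit on the remaining
    plants' pooled rates and the held-out plants are classified, yielding
    one :class:`MetricsReport` per fold.  Deterministic given the seed.
    ``return_folds`` additionally returns the held-out index arrays.
    """
    n = len(plant_rate_sets)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds plant count {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    reports = []
    for fold in folds:
        train_idx = np.setdiff1d(order, fold)
        pooled: dict[str, list[float]] = {CYLINDER: [], TOWER: []}
        for i in train_idx:
            label, rates = plant_rate_sets[i]
            pooled[label].extend(np.asarray(rates, dtype=float))
        intervals = fit_intervals(pooled, method=method)
        truth, predicted = [], []
        for i in fold:
            label, rates = plant_rate_sets[i]
            samples = [
                CornerRateSample(view_angle_deg=0.0, height=0.0, rate=float(r))
                for r in rates
            ]
            result = classify_plant(samples, intervals)
            truth.append(label)
            predicted.append(result.label)
        reports.append(metrics(confusion_from_labels(truth, predicted, positive)))
    if return_folds:
        return reports, [np.asarray(f) for f in folds]
    return reports
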