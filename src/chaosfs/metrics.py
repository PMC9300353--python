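"""Classification metrics, Friedman mean-rank comparison, final scoring.

The metric suite reports recall, precision, accuracy, F1, sensitivity,
specificity and balanced accuracy.  Binary problems use the confusion
counts of the positive class directly; multiclass problems use
one-vs-rest counts combined either ``weighted`` (by class support, the
default) or ``macro``.  Balanced accuracy is always the unweighted mean
over classes of (sensitivity + specificity) / 2 computed one-vs-rest.

Method comparison uses the Friedman test: methods are ranked within each
dataset (rank 1 = best score, ties share the average rank) and the ranks
averaged across datasets; the tie-corrected chi-square statistic and its
p-value accompany the mean ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .datasets import FeatureTable
from .selection import BinaryMask, make_classifier


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    recall: float
    precision: float
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    averaging_mode: str

    def as_dict(self) -> dict[str, float]:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }


@dataclass
class BenchmarkResult:
    """Per-method, per-dataset scores and their Friedman summary."""

    scores: pd.DataFrame  # rows = methods, columns = datasets
    ranks: pd.DataFrame | None = None
    mean_ranks: pd.Series | None = None
    statistic: float | None = None
    p_value: float | None = None


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``positive`` as the target."""
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0.0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(y_true, y_pred, averaging: str = "weighted") -> MetricsReport:
    """Metric suite from true and predicted labels.

    ``averaging``: ``binary`` (two classes; the larger sorted label is the
    positive class), ``weighted`` (one-vs-rest, support-weighted) or
    ``macro`` (one-vs-rest, unweighted).  Balanced accuracy is macro
    one-vs-rest (sensitivity + specificity) / 2 in every mode.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size == 0:
        raise ValueError("empty input")
    if averaging not in ("binary", "weighted", "macro"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if averaging == "binary" and len(classes) > 2:
        raise ValueError("binary averaging needs at most two classes")

    accuracy = float(np.mean(y_true == y_pred))

    per_class = []
    for c in classes:
        cc = confusion_counts(y_true, y_pred, positive=c)
        sens = _safe_div(cc.tp, cc.tp + cc.fn, f"sensitivity[{c}]")
        spec = _safe_div(cc.tn, cc.fp + cc.tn, f"specificity[{c}]")
        prec = _safe_div(cc.tp, cc.tp + cc.fp, f"precision[{c}]")
        f1 = _safe_div(2 * prec * sens, prec + sens, f"f1[{c}]")
        support = cc.tp + cc.fn
        per_class.append((sens, spec, prec, f1, support))
    per_class = np.array(per_class, float)
    balanced = float(np.mean((per_class[:, 0] + per_class[:, 1]) / 2.0))

    if averaging == "binary":
        positive = classes[-1]
        cc = confusion_counts(y_true, y_pred, positive=positive)
        sens = _safe_div(cc.tp, cc.tp + cc.fn, "sensitivity")
        spec = _safe_div(cc.tn, cc.fp + cc.tn, "specificity")
        prec = _safe_div(cc.tp, cc.tp + cc.fp, "precision")
        f1 = _safe_div(2 * prec * sens, prec + sens, "f1")
        balanced = (sens + spec) / 2.0
        return MetricsReport(
            recall=sens,
            precision=prec,
            accuracy=accuracy,
            f1=f1,
            sensitivity=sens,
            specificity=spec,
            balanced_accuracy=balanced,
            averaging_mode="binary",
        )

    weights = per_class[:, 4]
    if averaging == "weighted":
        weights = weights / weights.sum()
    else:
        weights = np.full(len(classes), 1.0 / len(classes))
    sens, spec, prec, f1 = (
        float(np.dot(weights, per_class[:, i])) for i in range(4)
    )
    return MetricsReport(
        recall=sens,
        precision=prec,
        accuracy=accuracy,
        f1=f1,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=balanced,
        averaging_mode=averaging,
    )


def friedman_statistic(ranks: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square and p-value from a rank matrix.

    ``ranks`` has shape (n_datasets, n_methods), each row a (possibly
    tied, average-rank) ranking of the methods on one dataset.
    """
    n, k = ranks.shape
    rank_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction: per dataset, sum of t^3 - t over tie groups
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:  # all methods tied everywhere
        return 0.0, 1.0
    chisq /= c
    return float(chisq), float(chi2.sf(chisq, k - 1))


def friedman_mean_ranks(
    scores: pd.DataFrame, higher_is_better: bool = True
) -> BenchmarkResult:
    """Friedman mean-rank comparison of methods across datasets.

    ``scores`` rows are methods, columns datasets; every cell must be
    present.  Rank 1 is the best score within each dataset; tied scores
    share the average rank.  Returns per-method mean ranks plus the
    Friedman statistic and p-value.
    """
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need >= 2 methods and >= 2 datasets")
    if scores.isna().any().any():
        missing = [
            (m, d) for m in scores.index for d in scores.columns
            if pd.isna(scores.loc[m, d])
        ]
        raise ValueError(f"missing cells: {missing}")
    sign = -1.0 if higher_is_better else 1.0
    ranks = np.vstack(
        [rankdata(sign * scores[col].to_numpy()) for col in scores.columns]
    )  # (n_datasets, n_methods)
    rank_df = pd.DataFrame(
        ranks.T, index=scores.index, columns=scores.columns
    )
    mean_ranks = rank_df.mean(axis=1)
    stat, p = friedman_statistic(ranks)
    return BenchmarkResult(
        scores=scores,
        ranks=rank_df,
        mean_ranks=mean_ranks,
        statistic=stat,
        p_value=p,
    )


def final_evaluate(
    table: FeatureTable,
    mask: BinaryMask,
    classifier_spec: str = "sgd",
    averaging: str = "weighted",
    classifier_seed: int = 0,
    return_predictions: bool = False,
):
    """Refit on the full training partition (selected columns only) and
    score the held-out test partition once.

    With ``return_predictions`` the test predictions come back alongside
    the report so callers can recount any metric from them.
    """
    if mask.selected_count == 0:
        raise ValueError("mask selects no features")
    x_train, y_train = table.partition("train")
    x_test, y_test = table.partition("test")
    unseen = set(np.unique(y_test)) - set(np.unique(y_train))
    if unseen:
        raise ValueError(
            f"test labels absent from training data: {sorted(unseen)}"
        )
    cols = mask.selected_indices
    clf = make_classifier(classifier_spec, classifier_seed)
    clf.fit(x_train[:, cols], y_train)
    y_pred = clf.predict(x_test[:, cols])
    report = compute_metrics(y_test, y_pred, averaging=averaging)
    if return_predictions:
        return report, y_pred
    return report
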