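"""Classifier-based evaluation of a selected feature subset.

The downstream model is always an (unpenalized) binomial logistic regression
fit on the training split; indicators are computed on the validation split:

* trapezoidal ROC AUC (equivalently the tie-corrected rank statistic),
* sensitivity and specificity at the cutoff maximizing Youden's index
  ``Se + Spe - 1``,
* counts of selected informative / non-informative features against the
  simulation truth, and
* Jaccard selection stability across repetitions.

Threshold scanning uses midpoints between consecutive distinct scores plus
sentinels below and above all scores; ties at the maximal Youden index are
resolved toward the lowest cutoff (the most sensitive operating point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .datasets import LabeledDataset

__all__ = ["MethodReport", "FittedLogistic", "fit_logistic", "roc_auc",
           "youden_point", "count_selected", "jaccard_stability"]


@dataclass
class MethodReport:
    """Per-method indicator vector feeding the multi-criteria ranking."""

    method: str
    auc: float
    sensitivity: float
    specificity: float
    nsif: float
    nsnif: float
    stability: float
    runtime_s: float


class FittedLogistic:
    """Binomial logistic model on a feature subset; intercept-only if empty.

    The positive class is the largest label code.  Perfect separation is
    accepted: the solver saturates the probabilities (a warning may be
    emitted by the optimizer).
    """

    def __init__(self, subset: Sequence[int], model, positive: int,
                 constant: float | None = None):
        self.subset = tuple(subset)
        self._model = model
        self.positive = positive
        self._constant = constant

    def predict_proba(self, data) -> np.ndarray:
        X = data.features if isinstance(data, LabeledDataset) else np.asarray(data, float)
        if self._constant is not None:
            return np.full(X.shape[0], self._constant)
        return self._model.predict_proba(X[:, list(self.subset)])[:, 1]


def fit_logistic(train: LabeledDataset, subset: Sequence[int]) -> FittedLogistic:
    """Maximum-likelihood logistic fit of class membership on ``subset``."""
    if train.n_classes != 2:
        raise ValueError("logistic evaluation requires binary labels")
    positive = train.n_classes  # largest code
    y = (train.labels == positive).astype(int)
    subset = list(subset)
    if not subset:
        return FittedLogistic((), None, positive, constant=float(y.mean()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = LogisticRegression(C=np.inf, max_iter=5000).fit(
            train.features[:, subset], y)
    return FittedLogistic(subset, model, positive)


def _binary_truth(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes present")
    return (y == classes.max()).astype(int)


def roc_auc(probs: np.ndarray, labels) -> float:
    """Trapezoidal area under the ROC curve; ties contribute 1/2."""
    y = _binary_truth(labels)
    return float(roc_auc_score(y, np.asarray(probs, float)))


def youden_point(probs: np.ndarray, labels) -> tuple[float, float]:
    """(sensitivity, specificity) at the Youden-optimal cutoff.

    With constant scores every cutoff has Youden index 0 and the lowest-cutoff
    rule returns (1.0, 0.0).
    """
    y = _binary_truth(labels)
    s = np.asarray(probs, float)
    uniq = np.unique(s)
    cuts = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    n_pos = y.sum()
    n_neg = y.size - n_pos
    best_j, best = -np.inf, (np.nan, np.nan)
    for t in cuts:   # ascending; strict > keeps the lowest maximizing cutoff
        pred = s > t
        se = float((pred & (y == 1)).sum()) / n_pos
        spe = float((~pred & (y == 0)).sum()) / n_neg
        if se + spe - 1.0 > best_j:
            best_j, best = se + spe - 1.0, (se, spe)
    return best


def count_selected(selected: Iterable[int], truth: Iterable[int],
                   p_total: int | None = None) -> tuple[int, int]:
    """(number of informative, number of non-informative) features selected."""
    sel, tru = set(selected), set(truth)
    if p_total is not None and sel and max(sel) >= p_total:
        raise ValueError("selected index out of range")
    return len(sel & tru), len(sel - tru)


def jaccard_stability(selections: Sequence[Iterable[int]]) -> float:
    """Mean pairwise Jaccard similarity of selected sets across repetitions.

    The (degenerate) empty-vs-empty pair has similarity 1.
    """
    sets = [set(s) for s in selections]
    R = len(sets)
    if R < 2:
        raise ValueError("stability needs at least two selections")
    total = 0.0
    for i in range(R - 1):
        for j in range(i + 1, R):
            union = sets[i] | sets[j]
            total += 1.0 if not union else len(sets[i] & sets[j]) / len(union)
    return 2.0 * total / (R * (R - 1))
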