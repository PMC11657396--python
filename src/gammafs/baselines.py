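"""Conventional feature-selection methods used as comparison baselines.

Filter scores implemented from their formulas:

* ``cramers_v_scores`` — Chi-squared association of each (discretized)
  feature with the class, reported as Cramér's V;
* ``su_scores`` — symmetrical uncertainty, the mutual information normalized
  by the sum of marginal entropies (base-2);
* ``cfs_select`` — correlation-based feature selection: the merit
  ``k r_cf / sqrt(k + k (k-1) r_ff)`` maximized by best-first search.

Ranking filters keep the head of the ranking up to the largest drop between
consecutive scores (``biggest_gap_cutoff``), so the number of selected
features is data-driven rather than fixed.

Model-based selectors are thin contracts over scikit-learn / statsmodels
fits: L1-penalized logistic regression with cross-validated penalty
(``lasso_select``), random-forest permutation importance with the gap cutoff
(``rfi_select``), bidirectional stepwise AIC logistic regression
(``step_aic_select``) and linear-SVM recursive feature elimination keeping
the subset with the best cross-validated accuracy (``svm_rfe_select``).

Continuous features are discretized by equal-frequency binning with
``max(2, ceil(log2 n) + 1)`` bins by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency, rankdata
from sklearn.exceptions import ConvergenceWarning

from .datasets import LabeledDataset
from .search import best_first_search

__all__ = ["RankedScores", "discretize", "default_bins", "cramers_v_scores",
           "su_scores", "symmetrical_uncertainty", "cfs_merit", "cfs_select",
           "biggest_gap_cutoff", "lasso_select", "rfi_select",
           "step_aic_select", "svm_rfe_select"]


@dataclass(frozen=True)
class RankedScores:
    """Per-feature importance scores with a descending order and a cutoff."""

    scores: np.ndarray          # (p,)
    order: np.ndarray           # permutation sorting scores descending
    cutoff_index: int           # keep order[:cutoff_index]

    @property
    def selected(self) -> list[int]:
        return sorted(int(j) for j in self.order[: self.cutoff_index])


def default_bins(n: int) -> int:
    return max(2, math.ceil(math.log2(n)) + 1)


def discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning into labels ``1..<=n_bins``.

    Ties are broken by value order (ordinal ranks); a constant vector
    collapses to a single bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.all(x == x[0]):
        return np.ones(n, dtype=int)
    ranks = rankdata(x, method="ordinal")
    return ((ranks - 1) * n_bins // n).astype(int) + 1


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((ua.size, ub.size), dtype=int)
    np.add.at(table, (ia, ib), 1)
    return table


def _cramers_v(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        return 0.0
    chi2 = chi2_contingency(table, correction=False).statistic
    n = table.sum()
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


def _ranked(scores: np.ndarray) -> RankedScores:
    order = np.argsort(-scores, kind="stable")
    cutoff = biggest_gap_cutoff(scores[order])
    return RankedScores(scores=scores, order=order, cutoff_index=cutoff)


def cramers_v_scores(data: LabeledDataset, n_bins: int | None = None) -> RankedScores:
    """Cramér's V of each discretized feature against the class."""
    n_bins = n_bins or default_bins(data.n)
    scores = np.array([
        _cramers_v(_contingency(discretize(data.features[:, j], n_bins), data.labels))
        for j in range(data.p)])
    return _ranked(scores)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _su_from_table(table: np.ndarray) -> float:
    hx = _entropy(table.sum(axis=1))
    hy = _entropy(table.sum(axis=0))
    if hx + hy == 0.0:
        return 0.0
    hxy = _entropy(table.ravel())
    ig = hx + hy - hxy
    return float(min(1.0, max(0.0, 2.0 * ig / (hx + hy))))


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU of two discrete vectors: ``2 IG(a; b) / (H(a) + H(b))`` in [0, 1]."""
    return _su_from_table(_contingency(a, b))


def su_scores(data: LabeledDataset, n_bins: int | None = None) -> RankedScores:
    """Symmetrical uncertainty of each discretized feature with the class."""
    n_bins = n_bins or default_bins(data.n)
    scores = np.array([
        symmetrical_uncertainty(discretize(data.features[:, j], n_bins), data.labels)
        for j in range(data.p)])
    return _ranked(scores)


def cfs_merit(subset, su_fc: np.ndarray, su_ff: np.ndarray) -> float:
    """CFS merit: high feature-class, low feature-feature association."""
    idx = np.asarray(list(subset), dtype=int)
    k = idx.size
    r_cf = su_fc[idx].mean()
    if k == 1:
        return float(r_cf)
    sub = su_ff[np.ix_(idx, idx)]
    r_ff = sub[~np.eye(k, dtype=bool)].mean()
    return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))


def cfs_select(data: LabeledDataset, n_bins: int | None = None,
               max_backtracks: int = 5) -> list[int]:
    """Correlation-based feature selection via best-first merit search."""
    n_bins = n_bins or default_bins(data.n)
    disc = np.column_stack([discretize(data.features[:, j], n_bins)
                            for j in range(data.p)])
    su_fc = np.array([symmetrical_uncertainty(disc[:, j], data.labels)
                      for j in range(data.p)])
    su_ff = np.eye(data.p)
    cache: dict[tuple[int, int], float] = {}

    def ff(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = symmetrical_uncertainty(disc[:, key[0]], disc[:, key[1]])
        return cache[key]

    def merit(subset) -> float:
        idx = sorted(subset)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                su_ff[idx[a], idx[b]] = su_ff[idx[b], idx[a]] = ff(idx[a], idx[b])
        return cfs_merit(idx, su_fc, su_ff)

    result = best_first_search(data.p, merit, max_backtracks=max_backtracks)
    return sorted(result.selected)


def biggest_gap_cutoff(scores_desc: np.ndarray) -> int:
    """Keep features up to the largest drop between consecutive scores."""
    s = np.asarray(scores_desc, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    if s.size == 1:
        return 1
    gaps = s[:-1] - s[1:]
    return int(np.argmax(gaps)) + 1          # first maximal gap on ties


def _binary_y(data: LabeledDataset) -> np.ndarray:
    if data.n_classes != 2:
        raise ValueError("this selector requires binary labels")
    return (data.labels == 2).astype(int)


def lasso_select(data: LabeledDataset, seed: int = 0, cv: int = 5,
                 n_penalties: int = 20) -> list[int]:
    """L1-penalized logistic regression; keep nonzero coefficients.

    The penalty strength is chosen by stratified cross-validated deviance
    with the one-standard-error rule: the strongest penalty whose mean CV
    deviance is within one standard error of the best.
    """
    from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    y = _binary_y(data)
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        search = LogisticRegressionCV(Cs=n_penalties, cv=cv, solver="liblinear",
                                      l1_ratios=[1.0], scoring="neg_log_loss",
                                      random_state=seed).fit(data.features, y)
        scores = search.scores_[1]              # (n_folds, n_Cs), higher = better
        mean, se = scores.mean(axis=0), scores.std(axis=0, ddof=1) / np.sqrt(cv)
        best = int(np.argmax(mean))
        # Cs_ ascends, so the first C whose score clears the 1-SE bar is the
        # strongest acceptable penalty
        chosen = int(np.flatnonzero(mean >= mean[best] - se[best])[0])
        model = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                   C=search.Cs_[chosen],
                                   random_state=seed).fit(data.features, y)
    return sorted(np.flatnonzero(np.abs(model.coef_[0]) > 0).tolist())


def rfi_select(data: LabeledDataset, seed: int = 0, n_estimators: int = 200,
               n_repeats: int = 5) -> list[int]:
    """Random-forest permutation importance ranking with the gap cutoff."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    y = _binary_y(data)
    forest = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=seed).fit(data.features, y)
    imp = permutation_importance(forest, data.features, y, n_repeats=n_repeats,
                                 random_state=seed, scoring="accuracy")
    return _ranked(imp.importances_mean).selected


def step_aic_select(data: LabeledDataset, max_steps: int | None = None) -> list[int]:
    """Bidirectional stepwise logistic regression minimizing AIC.

    Starts from the intercept-only model; at each step applies the single
    addition or removal that lowers the AIC the most, stopping when none do.
    """
    import statsmodels.api as sm

    y = _binary_y(data)
    X = data.features

    def aic_of(subset: tuple[int, ...]) -> float:
        design = sm.add_constant(X[:, list(subset)]) if subset else np.ones((data.n, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        return float(res.aic)

    current: tuple[int, ...] = ()
    current_aic = aic_of(current)
    max_steps = max_steps or 2 * data.p
    for _ in range(max_steps):
        best_move, best_aic = None, current_aic
        for j in range(data.p):
            cand = (tuple(sorted(set(current) - {j})) if j in current
                    else tuple(sorted(set(current) | {j})))
            a = aic_of(cand)
            if a < best_aic:
                best_move, best_aic = cand, a
        if best_move is None:
            break
        current, current_aic = best_move, best_aic
    return sorted(current)


def svm_rfe_select(data: LabeledDataset, seed: int = 0, cv: int = 5) -> list[int]:
    """Linear-SVM recursive feature elimination, one feature per round.

    The candidate subsets produced along the elimination path are compared by
    cross-validated accuracy; the smallest subset achieving the maximum wins.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.svm import LinearSVC

    y = _binary_y(data)
    X = data.features
    remaining = list(range(data.p))
    path = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while remaining:
            path.append(tuple(remaining))
            if len(remaining) == 1:
                break
            svc = LinearSVC(random_state=seed).fit(X[:, remaining], y)
            drop = int(np.argmin(np.abs(svc.coef_[0])))
            remaining = remaining[:drop] + remaining[drop + 1:]
        folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        best_set, best_acc = None, -np.inf
        for subset in reversed(path):          # smallest first; strict > keeps it on ties
            acc = cross_val_score(LinearSVC(random_state=seed), X[:, list(subset)],
                                  y, cv=folds, scoring="accuracy").mean()
            if acc > best_acc:
                best_set, best_acc = subset, acc
    return sorted(best_set)
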