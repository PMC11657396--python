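"""TOPSIS multi-criteria ranking of feature-selection methods.

Alternatives (methods) are scored by relative closeness to the ideal
solution: each criterion column is vector-normalized (divided by its
Euclidean norm), weighted, and compared to the per-criterion best (ideal)
and worst (anti-ideal) values, where "best" is the maximum for benefit
criteria and the minimum for cost criteria.  The score is
``d- / (d+ + d-)`` with Euclidean distances; rank 1 is the highest score.

The default weighting ranks the seven indicators AUC > sensitivity >
specificity > NSIF > NSNIF > stability > runtime with linearly decreasing
weights ``(8 - rank) / 28``; NSNIF and runtime are costs, the rest benefits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_CRITERIA", "default_weights", "topsis_scores", "DecisionMatrix"]

DEFAULT_CRITERIA = ("auc", "sensitivity", "specificity", "nsif", "nsnif",
                    "stability", "runtime_s")


def default_weights() -> tuple[np.ndarray, tuple[str, ...]]:
    """Standard indicator weights and benefit/cost categories.

    Weights are ``(8 - rank) / 28`` for ranks 1..7: 0.2500, 0.2143, 0.1786,
    0.1429, 0.1071, 0.0714, 0.0357 (summing to 1).
    """
    weights = (8.0 - np.arange(1, 8)) / 28.0
    categories = ("benefit", "benefit", "benefit", "benefit", "cost",
                  "benefit", "cost")
    return weights, categories


class DecisionMatrix:
    """Alternatives x criteria values with weights and categories."""

    def __init__(self, values, alternatives=None, criteria=None,
                 weights=None, categories=None):
        if isinstance(values, pd.DataFrame):
            alternatives = list(values.index) if alternatives is None else list(alternatives)
            criteria = list(values.columns) if criteria is None else list(criteria)
            values = values.to_numpy(dtype=float)
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("decision matrix must be 2-D")
        m, c = values.shape
        if weights is None or categories is None:
            dw, dc = default_weights()
            weights = dw if weights is None else weights
            categories = dc if categories is None else categories
        weights = np.asarray(weights, dtype=float)
        if weights.size != c or len(categories) != c:
            raise ValueError("weights/categories do not match criteria count")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if any(cat not in ("benefit", "cost") for cat in categories):
            raise ValueError("categories must be 'benefit' or 'cost'")
        self.values = values
        self.alternatives = list(alternatives) if alternatives is not None else list(range(m))
        self.criteria = list(criteria) if criteria is not None else list(range(c))
        self.weights = weights
        self.categories = tuple(categories)


def topsis_scores(matrix: DecisionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Closeness scores in [0, 1] and 1-based ranks (1 = best).

    Zero-norm criterion columns carry no information and are dropped with a
    warning.  If all alternatives coincide, every score is 0.5 by convention.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 alternatives")
    V = matrix.values
    norms = np.linalg.norm(V, axis=0)
    keep = norms > 0
    if not keep.all():
        dropped = [c for c, k in zip(matrix.criteria, keep) if not k]
        warnings.warn(f"dropping zero-norm criteria: {dropped}")
    V = V[:, keep] / norms[keep]
    W = V * matrix.weights[keep]
    cats = [c for c, k in zip(matrix.categories, keep) if k]
    ideal = np.where([c == "benefit" for c in cats], W.max(axis=0), W.min(axis=0))
    anti = np.where([c == "benefit" for c in cats], W.min(axis=0), W.max(axis=0))
    d_plus = np.linalg.norm(W - ideal, axis=1)
    d_minus = np.linalg.norm(W - anti, axis=1)
    denom = d_plus + d_minus
    scores = np.where(denom > 0, np.divide(d_minus, denom,
                                           out=np.full_like(denom, 0.5),
                                           where=denom > 0), 0.5)
    # rank 1 = highest score; stable tie-break by row order
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, scores.size + 1)
    return scores, ranks
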