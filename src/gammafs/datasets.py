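"""Labeled tabular datasets for class-separability scoring and feature selection.

A :class:`LabeledDataset` is the package's single in-memory container: an
``n x p`` numeric feature matrix plus a class label per observation.  Labels
may arrive as strings or arbitrary integers; they are mapped to consecutive
integer codes ``1..K`` in sorted order of the original values, which is the
convention every downstream routine (gamma-metric, selectors, evaluation)
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "load_csv"]


@dataclass(frozen=True)
class LabeledDataset:
    """Numeric feature matrix with class labels.

    Parameters
    ----------
    features:
        ``(n, p)`` float array. No missing values allowed.
    labels:
        Length-``n`` integer class codes in ``{1..K}``.
    feature_names:
        Length-``p`` column names.
    class_names:
        Original label values, index ``k-1`` giving the value mapped to
        code ``k``.  Defaults to the codes themselves.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = ()
    class_names: tuple = ()

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D array")
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        if y.shape != (n,):
            raise ValueError("labels length does not match features")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        codes = np.unique(y)
        if codes.size < 2:
            raise ValueError("need at least 2 classes")
        if not np.array_equal(codes, np.arange(1, codes.size + 1)):
            raise ValueError("labels must be consecutive integer codes 1..K "
                             "(use LabeledDataset.from_arrays to map raw labels)")
        counts = np.bincount(y)[1:]
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 observations")
        names = tuple(self.feature_names) or tuple(f"x{j + 1}" for j in range(p))
        if len(names) != p:
            raise ValueError("feature_names length does not match features")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(int))
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "class_names",
                           tuple(self.class_names) or tuple(int(c) for c in codes))

    # -- basic descriptors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def class_codes(self) -> np.ndarray:
        return np.arange(1, self.n_classes + 1)

    def class_counts(self) -> np.ndarray:
        """Observation count per class, index ``k-1`` for class ``k``."""
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    def class_rows(self, class_id: int) -> np.ndarray:
        """Feature rows belonging to ``class_id``."""
        if class_id not in self.class_codes:
            raise ValueError(f"unknown class {class_id!r}; classes are 1..{self.n_classes}")
        return self.features[self.labels == class_id]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_arrays(cls, X, y, feature_names: Sequence[str] | None = None) -> "LabeledDataset":
        """Build a dataset from raw labels (strings or ints), mapping them to 1..K."""
        y = np.asarray(y)
        values, codes = np.unique(y, return_inverse=True)
        return cls(np.asarray(X, dtype=float), codes + 1,
                   tuple(feature_names) if feature_names is not None else (),
                   tuple(values.tolist()))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str) -> "LabeledDataset":
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not in data")
        y = df[label_col].to_numpy()
        feats = df.drop(columns=[label_col])
        return cls.from_arrays(feats.to_numpy(dtype=float), y, feats.columns.tolist())

    def subset_matrix(self, subset: Sequence[int]) -> np.ndarray:
        return self.features[:, list(subset)]


def load_csv(path, label_col: str) -> LabeledDataset:
    """Read a header CSV where ``label_col`` holds the class labels."""
    return LabeledDataset.from_dataframe(pd.read_csv(path), label_col)
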