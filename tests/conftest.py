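import numpy as np
import pytest

from gammafs import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_blobs():
    """Well-separated spherical two-class dataset (means 0 and 10)."""
    rng = np.random.default_rng(7)
    n = 400
    X = np.vstack([rng.standard_normal((n, 3)),
                   rng.standard_normal((n, 3)) + 10.0])
    y = np.repeat([1, 2], n)
    return LabeledDataset(X, y)


def random_psd(rng, d):
    A = rng.standard_normal((d, d))
    return A @ A.T / d


def random_unit(rng, d):
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)
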