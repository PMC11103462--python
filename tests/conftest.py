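import numpy as np
import pytest

from optforest import FeatureTable
from optforest.forest import SubforestEvaluator


@pytest.fixture
def blob_data():
    """Factory for a well-separated two-Gaussian-blob classification set."""

    def make(n=400, seed=0, gap=4.0, n_features=5):
        rng = np.random.default_rng(seed)
        half = n // 2
        X = np.vstack(
            [
                rng.standard_normal((half, n_features)) + gap,
                rng.standard_normal((n - half, n_features)) - gap,
            ]
        )
        y = np.array(["A"] * half + ["B"] * (n - half), dtype=object)
        perm = rng.permutation(n)
        return X[perm], y[perm]

    return make


@pytest.fixture
def stub_evaluator():
    """Factory for an EA evaluator backed by fixed per-tree vote tables."""

    def make(n_trees=10, n_rows=20, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        tensor = np.zeros((n_trees, n_rows, n_classes))
        votes = rng.integers(0, n_classes, size=(n_trees, n_rows))
        tensor[np.arange(n_trees)[:, None], np.arange(n_rows)[None, :], votes] = 1.0
        y_codes = rng.integers(0, n_classes, size=n_rows)
        return SubforestEvaluator.from_tensor(tensor, y_codes)

    return make


@pytest.fixture
def tiny_table():
    """Four-row, two-feature table with one missing cell."""
    return FeatureTable(
        ["a", "b"],
        np.array([[1.0, 1.0], [np.nan, 0.0], [3.0, 1.0], [4.0, 0.0]]),
        np.array(["A", "A", "B", "B"], dtype=object),
        ["A", "B"],
    )
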