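"""Decision forests with per-tree quality scores and subforest voting.

The forest is induced random-forest style: each tree is CART trained on a
bootstrap resample with random feature-subspace splits. The bootstrap row
indices of every tree are recorded so that per-tree quality can be measured
on the tree's own out-of-bag rows — the rows its bootstrap never saw — which
keeps quality estimation independent of the validation fold later used as
the genetic algorithm's fitness data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "DecisionTreeModel",
    "Forest",
    "QualityStrata",
    "build_forest",
    "tree_quality",
    "stratify",
    "ensemble_predict",
    "ensemble_accuracy",
    "SubforestEvaluator",
]


class DecisionTreeModel:
    """One trained tree plus its bootstrap-sample row indices.

    The prediction contract is ``predict(X) -> labels`` and
    ``predict_scores(X) -> (n, C)`` per-class score vectors over the *full*
    class vocabulary (rows sum to 1), regardless of which classes the
    bootstrap sample happened to contain.
    """

    def __init__(self, estimator, bootstrap_idx: np.ndarray, classes: list):
        self.estimator = estimator
        self.bootstrap_idx = np.asarray(bootstrap_idx, dtype=int)
        self.classes = list(classes)

    def predict_scores(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((proba.shape[0], len(self.classes)))
        # estimator.classes_ holds integer codes into the full vocabulary
        out[:, self.estimator.classes_.astype(int)] = proba
        return out

    def predict(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        return np.asarray(self.classes, dtype=object)[scores.argmax(axis=1)]


@dataclass
class Forest:
    """T trained trees with aligned per-tree quality scores."""

    trees: list
    classes: list
    seed: int
    induction_params: dict = field(default_factory=dict)
    quality: np.ndarray | None = None
    quality_fallback: np.ndarray | None = None  # True where OOB was empty

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def score_tensor(self, X) -> np.ndarray:
        """Stacked per-tree score vectors, shape (T, n_rows, C)."""
        return np.stack([t.predict_scores(X) for t in self.trees])

    def encode_labels(self, y) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[v] for v in y], dtype=int)


@dataclass
class QualityStrata:
    """Partition of tree indices into three quality strata (best first)."""

    s1: list[int]
    s2: list[int]
    s3: list[int]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.s1), len(self.s2), len(self.s3)

    def as_lists(self) -> list[list[int]]:
        return [self.s1, self.s2, self.s3]


def build_forest(
    X,
    y,
    classes=None,
    n_trees: int = 100,
    seed: int = 0,
    max_features="sqrt",
    criterion: str = "gini",
    max_depth=None,
) -> Forest:
    """Train a bagged random-subspace CART forest.

    Each tree sees a bootstrap resample (indices recorded) and considers
    ``max_features`` candidate features per split (default √F), Gini
    impurity, unlimited depth. Deterministic given ``seed``.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    if np.isnan(X).any():
        raise ValueError("missing values present; impute first")
    if classes is None:
        classes = sorted(set(y))
    index = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([index[v] for v in y], dtype=int)
    if len(set(y_codes)) < 2:
        import warnings

        warnings.warn("single-class training data; trees are constant predictors",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    params = {
        "max_features": max_features,
        "criterion": criterion,
        "max_depth": max_depth,
    }
    trees = []
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        est = DecisionTreeClassifier(
            random_state=int(rng.integers(0, 2**31 - 1)), **params
        )
        est.fit(X[boot], y_codes[boot])
        trees.append(DecisionTreeModel(est, boot, classes))
    return Forest(trees=trees, classes=list(classes), seed=seed,
                  induction_params=params)


def tree_quality(forest: Forest, X, y) -> np.ndarray:
    """Per-tree quality = accuracy on the tree's out-of-bag rows.

    A tree whose bootstrap covered every row falls back to training accuracy
    (flagged in ``forest.quality_fallback``). Results are stored on the
    forest and returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = X.shape[0]
    quality = np.empty(forest.n_trees)
    fallback = np.zeros(forest.n_trees, dtype=bool)
    for t, tree in enumerate(forest.trees):
        oob = np.ones(n, dtype=bool)
        oob[tree.bootstrap_idx] = False
        rows = np.flatnonzero(oob)
        if rows.size == 0:
            rows = np.arange(n)
            fallback[t] = True
        pred = tree.predict(X[rows])
        quality[t] = float(np.mean(pred == y[rows]))
    forest.quality = quality
    forest.quality_fallback = fallback
    return quality


def stratify(quality, sizes) -> QualityStrata:
    """Partition tree indices into three strata by descending quality.

    Ties are broken by tree index (stable), so every stratum-1 quality is
    ≥ every stratum-2 quality ≥ every stratum-3 quality.
    """
    quality = np.asarray(quality, dtype=float)
    t = quality.size
    s1, s2, s3 = (int(s) for s in sizes)
    if s1 + s2 + s3 != t:
        raise ValueError(f"stratum sizes {sizes} do not sum to T={t}")
    order = np.lexsort((np.arange(t), -quality))
    return QualityStrata(
        list(map(int, order[:s1])),
        list(map(int, order[s1:s1 + s2])),
        list(map(int, order[s1 + s2:])),
    )


def ensemble_predict(forest: Forest, mask, X):
    """Soft-vote prediction of the subforest selected by ``mask``.

    The score vector is the mean of the selected trees' per-class scores;
    the predicted class is the argmax, ties resolved in vocabulary order.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty subforest mask")
    scores = np.mean(
        [forest.trees[t].predict_scores(X) for t in np.flatnonzero(mask)], axis=0
    )
    labels = np.asarray(forest.classes, dtype=object)[scores.argmax(axis=1)]
    return labels, scores


def ensemble_accuracy(forest: Forest, mask, X, y) -> float:
    """EA: fraction of rows the subforest vote classifies correctly.

    An empty mask scores 0 by convention (callers need not special-case it).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return 0.0
    labels, _ = ensemble_predict(forest, mask, X)
    return float(np.mean(labels == np.asarray(y, dtype=object)))


class SubforestEvaluator:
    """Cached EA evaluation of subforest masks on a fixed evaluation table.

    Per-tree score vectors on the evaluation rows are computed once
    (a (T, n, C) tensor), after which every mask costs one tensor reduction.
    """

    def __init__(self, forest: Forest, X, y):
        self.tensor = forest.score_tensor(X)
        self.y_codes = forest.encode_labels(np.asarray(y, dtype=object))
        self.n_trees = forest.n_trees
        self._cache: dict[bytes, float] = {}

    @classmethod
    def from_tensor(cls, tensor: np.ndarray, y_codes: np.ndarray):
        obj = cls.__new__(cls)
        obj.tensor = np.asarray(tensor, dtype=float)
        obj.y_codes = np.asarray(y_codes, dtype=int)
        obj.n_trees = obj.tensor.shape[0]
        obj._cache = {}
        return obj

    def ea(self, mask) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            return 0.0
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        mean_scores = self.tensor[mask].mean(axis=0)
        pred = mean_scores.argmax(axis=1)
        value = float(np.mean(pred == self.y_codes))
        self._cache[key] = value
        return value

    __call__ = ea
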