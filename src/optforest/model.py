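"""The optimized-forest classifier: a GA-pruned bagged decision forest."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .data_io import stratified_class_counts
from .forest import build_forest, ensemble_predict, tree_quality
from .ga import GAConfig, optimize_subforest

__all__ = ["OptimizedForestClassifier"]


class OptimizedForestClassifier(ClassifierMixin, BaseEstimator):
    """Decision forest pruned to its best subforest by a genetic algorithm.

    A bagged random-subspace CART forest of ``n_trees`` is induced on a
    stratified 1−``validation_fraction`` share of the training data; the
    held-in validation share supplies the GA's fitness, the ensemble
    accuracy (EA) of a candidate subforest. The GA seeds half its population
    with trees from the top quality strata (per-tree out-of-bag accuracy),
    evolves T-bit subforest masks by roulette selection, one-point
    crossover, single-bit mutation and elitism, and hill-climbs the
    incumbent best by single-bit flips (SSO). Prediction soft-votes the
    selected subforest.

    Parameters
    ----------
    n_trees : int, default 100
        Forest size T.
    n_iterations : int, default 30
        GA iterations J.
    population_size : int, default 20
        GA population |P|.
    m_trees : int or None
        Trees per initial chromosome M; None → ⌈T/5⌉.
    strata_sizes : tuple of 3 ints or None
        Quality stratum sizes |S1|,|S2|,|S3|; None → near-equal thirds.
    dss_fractions : tuple of 3 floats, default (0.6, 0.3, 0.1)
        Share of M drawn from each stratum for the stratified chromosomes.
    crossover_pairs : int, default 10
        Parent pairs per iteration (→ 2× offspring).
    validation_fraction : float, default 0.2
        Share of the training data held out as the GA's fitness fold.
    class_vocabulary : list or None
        Full class vocabulary (may include classes absent from ``y``);
        None → the sorted classes observed in ``y``.
    max_features, max_depth
        CART induction parameters (per split / per tree).
    sso_every_iteration, reseed_every_iteration : bool
        GA fidelity switches; see :class:`optforest.ga.GAConfig`.
    random_state : int or None
        Master seed; all internal streams derive from it.
    """

    def __init__(
        self,
        n_trees: int = 100,
        n_iterations: int = 30,
        population_size: int = 20,
        m_trees: int | None = None,
        strata_sizes=None,
        dss_fractions=(0.6, 0.3, 0.1),
        crossover_pairs: int = 10,
        validation_fraction: float = 0.2,
        class_vocabulary=None,
        max_features="sqrt",
        max_depth=None,
        sso_every_iteration: bool = True,
        reseed_every_iteration: bool = False,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.n_iterations = n_iterations
        self.population_size = population_size
        self.m_trees = m_trees
        self.strata_sizes = strata_sizes
        self.dss_fractions = dss_fractions
        self.crossover_pairs = crossover_pairs
        self.validation_fraction = validation_fraction
        self.class_vocabulary = class_vocabulary
        self.max_features = max_features
        self.max_depth = max_depth
        self.sso_every_iteration = sso_every_iteration
        self.reseed_every_iteration = reseed_every_iteration
        self.random_state = random_state

    def _split_validation(self, y, rng):
        """Stratified fit/validation row split (largest-remainder rounding)."""
        vocab = [c for c in self.classes_ if c in set(y)]
        counts = [int(np.sum(y == c)) for c in vocab]
        fit_counts = stratified_class_counts(counts, 1.0 - self.validation_fraction)
        fit_idx, val_idx = [], []
        for cls, k in zip(vocab, fit_counts):
            rows = np.flatnonzero(y == cls)
            perm = rng.permutation(rows)
            fit_idx.extend(perm[:k])
            val_idx.extend(perm[k:])
        return np.sort(fit_idx), np.sort(val_idx)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        y = np.asarray(y, dtype=object)
        if self.class_vocabulary is not None:
            vocab = list(self.class_vocabulary)
            missing = sorted(set(y) - set(vocab))
            if missing:
                raise ValueError(f"labels outside class_vocabulary: {missing}")
        else:
            vocab = sorted(set(y))
        self.classes_ = np.asarray(vocab, dtype=object)

        master = self.random_state if self.random_state is not None else 0
        seed_rng = np.random.default_rng(master)
        split_seed, forest_seed, ga_seed = seed_rng.integers(0, 2**31 - 1, size=3)

        fit_idx, val_idx = self._split_validation(
            y, np.random.default_rng(int(split_seed))
        )
        if len(val_idx) == 0:  # degenerate tiny input: validate on the fit rows
            val_idx = fit_idx
        X_fit, y_fit = X[fit_idx], y[fit_idx]
        X_val, y_val = X[val_idx], y[val_idx]

        forest = build_forest(
            X_fit,
            y_fit,
            classes=vocab,
            n_trees=self.n_trees,
            seed=int(forest_seed),
            max_features=self.max_features,
            max_depth=self.max_depth,
        )
        tree_quality(forest, X_fit, y_fit)
        config = GAConfig(
            population_size=self.population_size,
            iterations=self.n_iterations,
            m_trees=self.m_trees,
            strata_sizes=self.strata_sizes,
            dss_fractions=self.dss_fractions,
            crossover_pairs=self.crossover_pairs,
            seed=int(ga_seed),
            sso_every_iteration=self.sso_every_iteration,
            reseed_every_iteration=self.reseed_every_iteration,
        )
        best, trace = optimize_subforest(forest, X_val, y_val, config)
        self.forest_ = forest
        self.subforest_mask_ = best.bits
        self.validation_ea_ = best.ea
        self.trace_ = trace
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X = check_array(X, dtype=float)
        _, scores = ensemble_predict(self.forest_, self.subforest_mask_, X)
        return scores

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X = check_array(X, dtype=float)
        labels, _ = ensemble_predict(self.forest_, self.subforest_mask_, X)
        return labels
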