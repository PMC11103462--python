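"""Genetic-algorithm subforest selection.

A chromosome is a T-bit mask over the trees of a trained forest; its fitness
is the ensemble accuracy (EA) of the masked subforest on a validation table.
Each iteration applies roulette-wheel parent selection with one-point
crossover and single-bit mutation, an elitist exchange that preserves the
best chromosome found so far, roulette survivor selection from the pooled
parent+offspring populations, and a sequential-search rectification (SSO)
pass that greedily flips individual bits of the incumbent best whenever a
flip strictly improves EA.

The initial population is seeded half-and-half: ten chromosomes draw their
M trees by disproportionate stratified sampling (DSS) biased toward the
high-quality stratum, ten draw M trees uniformly from the whole forest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forest import Forest, QualityStrata, SubforestEvaluator, stratify

__all__ = [
    "GAConfig",
    "Chromosome",
    "GATrace",
    "dss_allocation",
    "init_population",
    "roulette_select",
    "one_point_crossover",
    "crossover_and_mutate",
    "elitist_update",
    "next_generation",
    "sso_rectify",
    "optimize",
    "optimize_subforest",
]


@dataclass
class GAConfig:
    """Hyperparameters of the subforest GA.

    ``m_trees`` defaults to ⌈T/5⌉ and ``strata_sizes`` to near-equal thirds;
    both are resolved against the forest size at run time. ``dss_fractions``
    split M across the three quality strata for the stratified half of the
    initial population.
    """

    population_size: int = 20
    iterations: int = 30
    m_trees: int | None = None
    strata_sizes: tuple[int, int, int] | None = None
    dss_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    crossover_pairs: int = 10
    seed: int = 0
    reseed_every_iteration: bool = False
    sso_every_iteration: bool = True

    def resolved_m(self, n_trees: int) -> int:
        m = self.m_trees if self.m_trees is not None else math.ceil(n_trees / 5)
        if m > n_trees:
            raise ValueError(f"m_trees={m} exceeds forest size {n_trees}")
        return m

    def resolved_strata_sizes(self, n_trees: int) -> tuple[int, int, int]:
        if self.strata_sizes is not None:
            return tuple(int(s) for s in self.strata_sizes)
        third = n_trees // 3
        return (n_trees - 2 * third, third, third)


@dataclass
class Chromosome:
    """A subforest mask with its cached validation EA."""

    bits: np.ndarray
    ea: float


@dataclass
class GATrace:
    """Per-iteration observability record of one optimization run."""

    best_ea_pcurr: list[float] = field(default_factory=list)
    best_ea_pmod: list[float] = field(default_factory=list)
    ea_sf_best: list[float] = field(default_factory=list)
    sso_flips: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ea_sf_best)


def dss_allocation(m: int, strata_sizes, fractions=(0.6, 0.3, 0.1)) -> list[int]:
    """Split M across three strata (best first), spilling overflow.

    Targets are round(f1·M), round(f2·M) and the remainder; an allocation
    exceeding its stratum is truncated with the overflow pushed to the next
    stratum (and back up if the last stratum also overflows).
    """
    sizes = [int(s) for s in strata_sizes]
    if m > sum(sizes):
        raise ValueError("M exceeds the number of trees")
    a1 = int(round(fractions[0] * m))
    a2 = int(round(fractions[1] * m))
    alloc = [a1, a2, m - a1 - a2]
    overflow = 0
    for i in range(3):
        alloc[i] += overflow
        overflow = max(alloc[i] - sizes[i], 0)
        alloc[i] = min(alloc[i], sizes[i])
    while overflow > 0:  # spill back up into remaining capacity
        for i in range(3):
            room = sizes[i] - alloc[i]
            take = min(room, overflow)
            alloc[i] += take
            overflow -= take
        if overflow and all(alloc[i] == sizes[i] for i in range(3)):
            break
    return alloc


def init_population(
    strata: QualityStrata, config: GAConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seed the population: odd positions by DSS, even positions uniformly.

    Every chromosome has exactly M set bits; stratified chromosomes draw
    round(0.6·M)/round(0.3·M)/remainder trees from strata S1/S2/S3 without
    replacement within a stratum.
    """
    n_trees = sum(strata.sizes)
    m = config.resolved_m(n_trees)
    alloc = dss_allocation(m, strata.sizes, config.dss_fractions)
    population = []
    for i in range(config.population_size):
        bits = np.zeros(n_trees, dtype=bool)
        if i % 2 == 1:  # stratified (DSS) chromosome
            for stratum, k in zip(strata.as_lists(), alloc):
                if k:
                    picks = rng.choice(len(stratum), size=k, replace=False)
                    bits[np.asarray(stratum)[picks]] = True
        else:  # uniform chromosome
            picks = rng.choice(n_trees, size=m, replace=False)
            bits[picks] = True
        population.append(bits)
    return population


def roulette_select(
    fitnesses,
    k: int,
    rng: np.random.Generator,
    replacement: bool = True,
) -> list[int]:
    """Fitness-proportional selection; returns indices into the candidates.

    Selection probability is EA/ΣEA (uniform when every fitness is zero).
    Without replacement, each winner is removed and the wheel renormalized.
    """
    fit = np.asarray(fitnesses, dtype=float)
    n = fit.size
    if n == 0:
        raise ValueError("empty candidate list")
    if not replacement and k > n:
        raise ValueError("k exceeds candidates without replacement")
    chosen: list[int] = []
    avail = list(range(n))
    for _ in range(k):
        weights = fit[avail]
        total = weights.sum()
        p = weights / total if total > 0 else np.full(len(avail), 1 / len(avail))
        pick = int(rng.choice(len(avail), p=p))
        chosen.append(avail[pick])
        if not replacement:
            avail.pop(pick)
    return chosen


def one_point_crossover(
    p1: np.ndarray, p2: np.ndarray, cut: int
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the suffixes of two parents at ``cut`` (1 ≤ cut ≤ T−1)."""
    if not 1 <= cut <= p1.size - 1:
        raise ValueError("cut point must lie strictly inside the chromosome")
    c1 = np.concatenate([p1[:cut], p2[cut:]])
    c2 = np.concatenate([p2[:cut], p1[cut:]])
    return c1, c2


def crossover_and_mutate(
    pcurr: list[np.ndarray],
    config: GAConfig,
    rng: np.random.Generator,
    evaluator,
) -> list[np.ndarray]:
    """Produce the offspring population PMod.

    ``crossover_pairs`` parent pairs are drawn by roulette (pairs with
    replacement; the two parents of a pair distinct). Each pair undergoes
    one-point crossover at a uniform cut in [1, T−1]; each offspring then has
    exactly one uniformly chosen bit flipped.
    """
    if len(pcurr) < 2:
        raise ValueError("need at least two chromosomes for crossover")
    fitness = [evaluator(c) for c in pcurr]
    t = pcurr[0].size
    offspring: list[np.ndarray] = []
    for _ in range(config.crossover_pairs):
        a, b = roulette_select(fitness, 2, rng, replacement=False)
        cut = int(rng.integers(1, t)) if t > 1 else 1
        child1, child2 = one_point_crossover(pcurr[a], pcurr[b], cut)
        for child in (child1, child2):
            flip = int(rng.integers(t))
            child[flip] = ~child[flip]
            offspring.append(child)
    return offspring


def _argbest(population: list[np.ndarray], evaluator) -> int:
    scores = [evaluator(c) for c in population]
    return int(np.argmax(scores))


def elitist_update(
    pcurr: list[np.ndarray],
    pmod: list[np.ndarray],
    state: dict,
    evaluator,
) -> dict:
    """Elitist exchange between the parent and offspring populations.

    Stores the parent best as CrCurrBest; promotes the offspring best to
    CrSFBest when strictly better; injects CrCurrBest over the worst
    offspring when strictly better; finally recomputes CrCurrBest over the
    modified offspring population. Ties never trigger replacement. ``pmod``
    is modified in place.
    """
    if not pcurr or not pmod:
        raise ValueError("empty population")
    i_curr = _argbest(pcurr, evaluator)
    cr_curr_best = pcurr[i_curr].copy()
    ea_curr_best = evaluator(cr_curr_best)

    i_mod = _argbest(pmod, evaluator)
    ea_mod_best = evaluator(pmod[i_mod])
    if state.get("cr_sf_best") is None or ea_mod_best > state["ea_sf_best"]:
        state["cr_sf_best"] = pmod[i_mod].copy()
        state["ea_sf_best"] = ea_mod_best

    mod_fitness = [evaluator(c) for c in pmod]
    i_worst = int(np.argmin(mod_fitness))
    if ea_curr_best > mod_fitness[i_worst]:
        pmod[i_worst] = cr_curr_best.copy()

    i_mod = _argbest(pmod, evaluator)
    state["cr_curr_best"] = pmod[i_mod].copy()
    state["ea_curr_best"] = evaluator(pmod[i_mod])
    return state


def next_generation(
    pcurr: list[np.ndarray],
    pmod: list[np.ndarray],
    rng: np.random.Generator,
    evaluator,
    population_size: int = 20,
) -> list[np.ndarray]:
    """Pool parents and offspring, roulette-select survivors w/o replacement."""
    pool = list(pcurr) + list(pmod)
    fitness = [evaluator(c) for c in pool]
    keep = roulette_select(fitness, population_size, rng, replacement=False)
    return [pool[i].copy() for i in keep]


def sso_rectify(bits: np.ndarray, evaluator) -> tuple[np.ndarray, int]:
    """Greedy per-bit rectification of a chromosome (SSO).

    One pass over the set bits in ascending index order flips 1→0, keeping a
    flip only when EA strictly improves; then one pass over the clear bits
    flips 0→1 likewise. A flip that would empty the chromosome is never
    accepted. Returns the rectified chromosome and the number of kept flips.
    """
    working = np.asarray(bits, dtype=bool).copy()
    best_ea = evaluator(working)
    flips = 0
    for j in np.flatnonzero(working):
        if working.sum() == 1:
            break
        working[j] = False
        ea = evaluator(working)
        if ea > best_ea:
            best_ea = ea
            flips += 1
        else:
            working[j] = True
    for j in np.flatnonzero(~working):
        working[j] = True
        ea = evaluator(working)
        if ea > best_ea:
            best_ea = ea
            flips += 1
        else:
            working[j] = False
    return working, flips


def optimize(
    evaluator,
    strata: QualityStrata,
    config: GAConfig,
) -> tuple[Chromosome, GATrace]:
    """Run the full GA and return the best subforest chromosome and trace.

    ``evaluator`` maps a T-bit mask to its validation EA. The population is
    seeded once (iteration 1); a literal mode that re-randomizes it every
    iteration is available via ``config.reseed_every_iteration``. SSO is
    applied to the incumbent best each iteration by default, or only after
    the final iteration with ``sso_every_iteration=False``. Fully
    deterministic given ``config.seed``: each stochastic component draws
    from its own stream derived from the master seed.
    """
    if config.iterations < 1:
        raise ValueError("iterations must be >= 1")
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_init = np.random.default_rng(streams[0])
    rng_cx = np.random.default_rng(streams[1])
    rng_sel = np.random.default_rng(streams[2])

    pcurr = init_population(strata, config, rng_init)
    i0 = _argbest(pcurr, evaluator)
    state = {"cr_sf_best": pcurr[i0].copy(), "ea_sf_best": evaluator(pcurr[i0])}
    trace = GATrace()
    for j in range(config.iterations):
        if config.reseed_every_iteration and j > 0:
            pcurr = init_population(strata, config, rng_init)
        pmod = crossover_and_mutate(pcurr, config, rng_cx, evaluator)
        state = elitist_update(pcurr, pmod, state, evaluator)
        pcurr = next_generation(
            pcurr, pmod, rng_sel, evaluator, config.population_size
        )
        flips = 0
        if config.sso_every_iteration:
            rect, flips = sso_rectify(state["cr_sf_best"], evaluator)
            state["cr_sf_best"], state["ea_sf_best"] = rect, evaluator(rect)
        trace.best_ea_pcurr.append(max(evaluator(c) for c in pcurr))
        trace.best_ea_pmod.append(max(evaluator(c) for c in pmod))
        trace.ea_sf_best.append(state["ea_sf_best"])
        trace.sso_flips.append(flips)
    if not config.sso_every_iteration:
        rect, flips = sso_rectify(state["cr_sf_best"], evaluator)
        state["cr_sf_best"], state["ea_sf_best"] = rect, evaluator(rect)
        trace.sso_flips[-1] = flips
        trace.ea_sf_best[-1] = state["ea_sf_best"]
    best = Chromosome(bits=state["cr_sf_best"], ea=state["ea_sf_best"])
    return best, trace


def optimize_subforest(
    forest: Forest,
    X_val,
    y_val,
    config: GAConfig,
) -> tuple[Chromosome, GATrace]:
    """Convenience wrapper: derive quality strata and run :func:`optimize`.

    Tree quality (OOB accuracy) must already be attached to the forest via
    :func:`optforest.forest.tree_quality`; EA is evaluated on the supplied
    validation table, never on the data the trees were induced from.
    """
    if forest.quality is None:
        raise ValueError("call tree_quality(forest, X_train, y_train) first")
    sizes = config.resolved_strata_sizes(forest.n_trees)
    strata = stratify(forest.quality, sizes)
    evaluator = SubforestEvaluator(forest, X_val, y_val)
    return optimize(evaluator, strata, config)
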