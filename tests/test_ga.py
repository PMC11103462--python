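import numpy as np
import pytest

from optforest import build_forest, stratify, tree_quality
from optforest.forest import QualityStrata, SubforestEvaluator
from optforest.ga import (
    GAConfig,
    crossover_and_mutate,
    dss_allocation,
    elitist_update,
    init_population,
    next_generation,
    one_point_crossover,
    optimize,
    optimize_subforest,
    roulette_select,
    sso_rectify,
)


def dict_evaluator(table: dict):
    """EA evaluator with prescribed fitness per mask (keyed by bit bytes)."""

    def ea(mask):
        return table[np.asarray(mask, dtype=bool).tobytes()]

    return ea


def mask(bits: str) -> np.ndarray:
    return np.array([b == "1" for b in bits])


class TestInitPopulation:
    def test_sizes_and_bit_counts(self):
        strata = QualityStrata(list(range(34)), list(range(34, 67)),
                               list(range(67, 100)))
        cfg = GAConfig(m_trees=20)
        pop = init_population(strata, cfg, np.random.default_rng(0))
        assert len(pop) == 20
        assert all(int(c.sum()) == 20 for c in pop)

    def test_dss_chromosomes_follow_allocation(self):
        strata = QualityStrata(list(range(34)), list(range(34, 67)),
                               list(range(67, 100)))
        cfg = GAConfig(m_trees=20)
        pop = init_population(strata, cfg, np.random.default_rng(1))
        s1, s2, s3 = set(strata.s1), set(strata.s2), set(strata.s3)
        for i in range(1, 20, 2):  # stratified chromosomes at odd positions
            chosen = set(np.flatnonzero(pop[i]))
            assert len(chosen & s1) == 12  # round(0.6 × 20)
            assert len(chosen & s2) == 6   # round(0.3 × 20)
            assert len(chosen & s3) == 2   # remainder

    def test_dss_allocation_spills_overflow(self):
        assert dss_allocation(20, (34, 33, 33)) == [12, 6, 2]
        assert dss_allocation(10, (2, 3, 20)) == [2, 3, 5]

    def test_m_larger_than_forest_rejected(self):
        strata = QualityStrata([0, 1], [2], [3])
        with pytest.raises(ValueError):
            init_population(strata, GAConfig(m_trees=9), np.random.default_rng(0))


class TestRouletteSelect:
    def test_dominant_fitness_always_selected(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert roulette_select([0, 1.0, 0], 1, rng) == [1]

    def test_equal_fitness_uniform_within_3_sigma(self):
        rng = np.random.default_rng(1)
        draws = 10_000
        picks = [roulette_select([0.3] * 4, 1, rng)[0] for _ in range(draws)]
        freq = np.bincount(picks, minlength=4) / draws
        sigma = np.sqrt(0.25 * 0.75 / draws)
        assert np.all(np.abs(freq - 0.25) < 3 * sigma)

    def test_proportional_frequencies(self):
        rng = np.random.default_rng(2)
        draws = 10_000
        picks = [roulette_select([0.2, 0.8], 1, rng)[0] for _ in range(draws)]
        freq1 = np.mean(np.asarray(picks) == 1)
        sigma = np.sqrt(0.8 * 0.2 / draws)
        assert abs(freq1 - 0.8) < 3 * sigma

    def test_without_replacement_distinct(self):
        rng = np.random.default_rng(3)
        sel = roulette_select([0.1, 0.2, 0.3, 0.4], 4, rng, replacement=False)
        assert sorted(sel) == [0, 1, 2, 3]

    def test_all_zero_fitness_uniform(self):
        rng = np.random.default_rng(4)
        sel = roulette_select([0.0, 0.0], 2, rng, replacement=False)
        assert sorted(sel) == [0, 1]


class TestCrossoverMutation:
    def test_one_point_crossover_hand_example(self):
        c1, c2 = one_point_crossover(mask("1111"), mask("0000"), cut=2)
        assert "".join("1" if b else "0" for b in c1) == "1100"
        assert "".join("1" if b else "0" for b in c2) == "0011"

    def test_offspring_count_and_mutation_distance(self):
        rng = np.random.default_rng(5)
        pcurr = [mask("11110000"), mask("00001111"), mask("10101010"),
                 mask("01010101")]
        ev = lambda c: float(c.sum())  # noqa: E731
        pmod = crossover_and_mutate(pcurr, GAConfig(crossover_pairs=10), rng, ev)
        assert len(pmod) == 20
        # each offspring is exactly 1 flip away from a pure one-point cross
        t = 8
        pure = set()
        for i, a in enumerate(pcurr):
            for b in pcurr[i + 1:]:
                for cut in range(1, t):
                    x, y = one_point_crossover(a, b, cut)
                    pure.add(x.tobytes())
                    pure.add(y.tobytes())
        for child in pmod:
            dists = []
            for p in pure:
                pm = np.frombuffer(p, dtype=bool)
                dists.append(int((pm ^ child).sum()))
            assert min(dists) <= 1


class TestElitistUpdate:
    def test_hand_traced_exchange(self):
        a, b, c, d, e = (mask(s) for s in
                         ("1000", "0100", "0010", "0001", "1100"))
        ev = dict_evaluator({
            a.tobytes(): 0.6, b.tobytes(): 0.5,
            c.tobytes(): 0.4, d.tobytes(): 0.3, e.tobytes(): 0.55,
        })
        pmod = [c.copy(), d.copy()]
        state = {"cr_sf_best": e.copy(), "ea_sf_best": 0.55}
        state = elitist_update([a.copy(), b.copy()], pmod, state, ev)
        assert state["ea_sf_best"] == 0.55          # 0.4 does not beat 0.55
        assert np.array_equal(pmod[1], a)           # worst (.3) replaced by .6
        assert state["ea_curr_best"] == 0.6         # recomputed over new pmod

    def test_sf_best_promoted_when_offspring_better(self):
        a, b = mask("10"), mask("01")
        ev = dict_evaluator({a.tobytes(): 0.9, b.tobytes(): 0.7})
        state = {"cr_sf_best": b.copy(), "ea_sf_best": 0.7}
        state = elitist_update([b.copy()], [a.copy()], state, ev)
        assert state["ea_sf_best"] == 0.9

    def test_monotone_sf_best(self, stub_evaluator):
        ev = stub_evaluator(n_trees=6, seed=2)
        rng = np.random.default_rng(0)
        pcurr = [rng.random(6) < 0.5 for _ in range(4)]
        pmod = [rng.random(6) < 0.5 for _ in range(4)]
        best0 = max(ev.ea(c) for c in pcurr)
        state = {"cr_sf_best": pcurr[0].copy(), "ea_sf_best": ev.ea(pcurr[0])}
        before = state["ea_sf_best"]
        state = elitist_update(pcurr, pmod, state, ev)
        assert state["ea_sf_best"] >= before
        del best0


class TestNextGeneration:
    def test_size_and_membership(self, stub_evaluator):
        ev = stub_evaluator(n_trees=8, seed=1)
        rng = np.random.default_rng(1)
        pcurr = [rng.random(8) < 0.5 for _ in range(20)]
        pmod = [rng.random(8) < 0.5 for _ in range(20)]
        new = next_generation(pcurr, pmod, rng, ev.ea, population_size=20)
        assert len(new) == 20
        pool = {c.tobytes() for c in pcurr} | {c.tobytes() for c in pmod}
        assert all(c.tobytes() in pool for c in new)

    def test_top_fitness_always_survives(self):
        star = mask("1111")
        rest = [mask("1000"), mask("0100"), mask("0010")]
        table = {star.tobytes(): 1.0}
        table.update({c.tobytes(): 0.0 for c in rest})
        ev = dict_evaluator(table)
        for seed in range(10):
            new = next_generation([star] + rest[:1], rest[1:], np.
                                  random.default_rng(seed), ev,
                                  population_size=2)
            assert any(np.array_equal(c, star) for c in new)


class TestSSORectify:
    def test_drops_tree_that_poisons_the_vote(self):
        # trees 0-1 score (0.6, 0.4) on the true class, tree 2 scores (0, 1):
        # all three together predict the wrong class, so SSO must drop tree 2
        n = 4
        tensor = np.zeros((3, n, 2))
        tensor[0, :, :] = [0.6, 0.4]
        tensor[1, :, :] = [0.6, 0.4]
        tensor[2, :, :] = [0.0, 1.0]
        ev = SubforestEvaluator.from_tensor(tensor, np.zeros(n, dtype=int))
        out, flips = sso_rectify(mask("111"), ev.ea)
        assert np.array_equal(out, mask("110"))
        assert flips == 1 and ev.ea(out) == 1.0

    def test_no_improving_flip_is_identity(self, stub_evaluator):
        ev = stub_evaluator(n_trees=5, seed=3)
        # rectify twice: second pass can find no further improving flip
        first, _ = sso_rectify(mask("10101"), ev.ea)
        second, flips = sso_rectify(first, ev.ea)
        assert np.array_equal(first, second) and flips == 0

    def test_never_decreases_ea_and_never_empties(self, stub_evaluator):
        for seed in range(5):
            ev = stub_evaluator(n_trees=7, seed=seed)
            rng = np.random.default_rng(seed)
            start = rng.random(7) < 0.3
            if not start.any():
                start[0] = True
            out, _ = sso_rectify(start, ev.ea)
            assert ev.ea(out) >= ev.ea(start)
            assert out.any()


class TestOptimize:
    def test_trace_length_monotonicity_determinism(self, stub_evaluator):
        ev = stub_evaluator(n_trees=12, seed=0)
        strata = stratify(np.random.default_rng(0).random(12), (4, 4, 4))
        cfg = GAConfig(iterations=15, m_trees=3, seed=7)
        best1, trace1 = optimize(ev.ea, strata, cfg)
        best2, trace2 = optimize(ev.ea, strata, cfg)
        assert len(trace1) == 15
        series = trace1.ea_sf_best
        assert all(x <= y + 1e-12 for x, y in zip(series, series[1:]))
        assert np.array_equal(best1.bits, best2.bits)
        assert trace1.ea_sf_best == trace2.ea_sf_best

    def test_sf_best_never_below_initial_population(self, stub_evaluator):
        ev = stub_evaluator(n_trees=10, seed=4)
        strata = stratify(np.random.default_rng(1).random(10), (4, 3, 3))
        cfg = GAConfig(iterations=5, m_trees=2, seed=3)
        # reconstruct the initial population from the same derived stream
        streams = np.random.SeedSequence(cfg.seed).spawn(3)
        pop0 = init_population(strata, cfg, np.random.default_rng(streams[0]))
        best, trace = optimize(ev.ea, strata, cfg)
        assert best.ea >= max(ev.ea(c) for c in pop0) - 1e-12

    def test_beats_mean_of_random_masks_on_blobs(self, blob_data):
        X, y = blob_data(n=400, seed=1)
        forest = build_forest(X, y, n_trees=30, seed=1)
        tree_quality(forest, X, y)
        cfg = GAConfig(iterations=10, m_trees=6, seed=1)
        best, _ = optimize_subforest(forest, X, y, cfg)
        ev = SubforestEvaluator(forest, X, y)
        rng = np.random.default_rng(2)
        rand = [
            ev.ea(np.isin(np.arange(30), rng.choice(30, 6, replace=False)))
            for _ in range(50)
        ]
        assert best.ea >= np.mean(rand)

    def test_rejects_zero_iterations(self, stub_evaluator):
        ev = stub_evaluator()
        strata = stratify(np.zeros(10), (4, 3, 3))
        with pytest.raises(ValueError):
            optimize(ev.ea, strata, GAConfig(iterations=0))
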