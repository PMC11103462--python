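import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optforest import FeatureTable
from optforest.feature_selection import (
    ARRHYTHMIA_SUBSET_BEST_FIRST,
    ARRHYTHMIA_SUBSET_CONSENSUS_PRINTED,
    ARRHYTHMIA_SUBSET_HARMONY,
    ARRHYTHMIA_SUBSET_PSO,
    BestFirstConfig,
    HarmonyConfig,
    MeritComponents,
    PSOConfig,
    best_first_select,
    brute_force_best_subset,
    cfs_merit_score,
    compute_merit,
    consistency_score,
    harmony_search_select,
    majority_vote,
    predictive_power,
    pso_select,
    pso_velocity_update,
    redundancy,
)


def table(values, labels):
    values = np.asarray(values, dtype=float)
    names = [f"f{i}" for i in range(values.shape[1])]
    vocab = sorted(set(labels))
    return FeatureTable(names, values, np.asarray(labels, dtype=object), vocab)


def random_merit(seed, n_features=10, n_rows=60, n_classes=3, n_informative=3):
    """Merit table derived from a random small data table with a few
    informative features — the distribution used for search-vs-oracle runs."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, n_rows)
    X = rng.standard_normal((n_rows, n_features))
    for j in range(n_informative):
        X[:, j] += 1.0 * y
    return compute_merit(X, y)


class TestPredictivePower:
    def test_perfect_separation(self):
        t = table([[0], [0], [1], [1]], list("AABB"))
        assert predictive_power(t, "f0") == 1.0

    def test_equal_class_means(self):
        t = table([[0], [1], [0], [1]], list("AABB"))
        assert predictive_power(t, "f0") == 0.0

    def test_hand_anova_value(self):
        # values 0..3, classes AABB: SS_between = 4, SS_total = 5
        t = table([[0], [1], [2], [3]], list("AABB"))
        assert predictive_power(t, "f0") == pytest.approx(np.sqrt(4 / 5), abs=1e-12)

    def test_constant_feature_and_errors(self):
        t = table([[5], [5], [5], [5]], list("AABB"))
        assert predictive_power(t, "f0") == 0.0
        with pytest.raises(KeyError):
            predictive_power(t, "nope")


class TestRedundancy:
    def test_self_and_negation(self):
        t = table([[1, -1], [2, -2], [3, -3]], list("AAB"))
        assert redundancy(t, "f0", "f0") == pytest.approx(1.0)
        assert redundancy(t, "f0", "f1") == pytest.approx(1.0)

    def test_hand_pearson(self):
        t = table([[1, 1], [2, 0], [3, 1], [4, 0]], list("AABB"))
        assert redundancy(t, "f0", "f1") == pytest.approx(1 / np.sqrt(5), abs=1e-12)

    def test_constant_column_convention(self):
        t = table([[1, 7], [2, 7], [3, 7]], list("AAB"))
        assert redundancy(t, "f0", "f1") == 0.0


class TestConsistencyScore:
    def test_singleton_is_one(self):
        m = MeritComponents(["a"], [0.3], [[1.0]])
        assert consistency_score(m, ["a"]) == 1.0

    def test_pair_ordered_sum_convention(self):
        # IP 0.5 each, R=0.5: TP=1.0, TR counts both ordered pairs = 1.0
        m = MeritComponents(["a", "b"], [0.5, 0.5], [[1, 0.5], [0.5, 1]])
        assert consistency_score(m, ["a", "b"]) == pytest.approx(0.5)

    def test_empty_and_degenerate(self):
        m = MeritComponents(["a"], [0.0], [[1.0]])
        assert consistency_score(m, []) == 0.0
        assert consistency_score(m, ["a"]) == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_removing_zero_ip_redundant_feature_never_hurts(self, seed):
        rng = np.random.default_rng(seed)
        f = 5
        ip = rng.random(f)
        ip[0] = 0.0
        r = rng.random((f, f)) * 0.5 + 0.25
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        m = MeritComponents([f"f{i}" for i in range(f)], ip, r)
        full = [f"f{i}" for i in range(f)]
        reduced = full[1:]
        assert consistency_score(m, reduced) >= consistency_score(m, full)


class TestBruteForce:
    def test_single_feature(self):
        m = MeritComponents(["a"], [0.4], [[1.0]])
        subset, score = brute_force_best_subset(m)
        assert subset == frozenset(["a"]) and score == 1.0

    def test_three_feature_hand_enumeration(self):
        # CFS merit, hand-enumerated over the 7 non-empty subsets:
        # ips (.8,.7,.1), all pairwise R = 0.05
        m = MeritComponents(
            ["a", "b", "c"],
            [0.8, 0.7, 0.1],
            [[1, 0.05, 0.05], [0.05, 1, 0.05], [0.05, 0.05, 1]],
        )
        subset, score = brute_force_best_subset(m, objective="cfs")
        # {a,b}: 1.5/sqrt(2+0.1)=1.0351 beats {a}=0.8, {a,b,c}=1.6/sqrt(3.3)=0.8807
        assert subset == frozenset(["a", "b"])
        assert score == pytest.approx(1.5 / np.sqrt(2.1), abs=1e-12)

    def test_guard_on_large_f(self):
        f = 21
        m = MeritComponents([f"f{i}" for i in range(f)], np.ones(f), np.eye(f))
        with pytest.raises(ValueError):
            brute_force_best_subset(m)


class TestSearches:
    @pytest.mark.parametrize("objective", ["consistency", "cfs"])
    def test_search_never_beats_oracle(self, objective):
        for seed in range(8):
            m = random_merit(seed, n_features=8)
            _, opt = brute_force_best_subset(m, objective=objective)
            for subset in (
                harmony_search_select(m, seed=seed, objective=objective),
                best_first_select(m, objective=objective),
                pso_select(m, seed=seed, objective=objective),
            ):
                score = (
                    consistency_score(m, m.index_of(subset))
                    if objective == "consistency"
                    else cfs_merit_score(m, m.index_of(subset))
                )
                assert score <= opt + 1e-12

    def test_harmony_deterministic_and_zero_iterations(self):
        m = random_merit(1)
        cfg = HarmonyConfig(iterations=0)
        a = harmony_search_select(m, cfg, seed=4)
        b = harmony_search_select(m, cfg, seed=4)
        assert a == b
        refined = harmony_search_select(m, HarmonyConfig(iterations=200), seed=4)
        assert consistency_score(m, m.index_of(refined)) >= consistency_score(
            m, m.index_of(a)
        )

    def test_harmony_single_feature_table(self):
        m = MeritComponents(["only"], [0.6], [[1.0]])
        assert harmony_search_select(m, seed=0) == frozenset(["only"])

    def test_best_first_empty_when_all_ip_zero(self):
        m = MeritComponents(["a", "b"], [0.0, 0.0], [[1, 0.3], [0.3, 1]])
        assert best_first_select(m) == frozenset()

    def test_best_first_contains_top_ip_feature(self):
        m = MeritComponents(
            ["a", "b", "c"], [0.9, 0.2, 0.1], np.eye(3)
        )
        assert "a" in best_first_select(m)

    def test_best_first_matches_oracle_on_separable_merit(self):
        # mutually uncorrelated features: greedy = exhaustive optimum
        m = MeritComponents(
            [f"f{i}" for i in range(6)],
            [0.9, 0.8, 0.7, 0.05, 0.04, 0.03],
            np.eye(6),
        )
        subset = best_first_select(m, objective="cfs")
        oracle, _ = brute_force_best_subset(m, objective="cfs")
        assert subset == oracle

    def test_pso_deterministic(self):
        m = random_merit(2)
        assert pso_select(m, seed=9) == pso_select(m, seed=9)

    def test_velocity_update_identities(self):
        cfg = PSOConfig(w=1.0, c1=0.0, c2=0.0)
        v = np.array([0.5, -1.0])
        x = np.array([1, 0])
        out = pso_velocity_update(v, x, x, x, cfg, np.array([0.3, 0.7]),
                                  np.array([0.2, 0.9]))
        assert np.allclose(out, v)  # w=1, c1=c2=0 leaves velocity unchanged
        cfg0 = PSOConfig(w=0.0)
        out0 = pso_velocity_update(v, x, x, x, cfg0, np.array([0.3, 0.7]),
                                   np.array([0.2, 0.9]))
        assert np.allclose(out0, 0.0)  # x = p_best = g_best, w=0
        cfg_clip = PSOConfig(w=1.0, c1=0.0, c2=0.0, v_max=0.25)
        assert np.allclose(
            pso_velocity_update(v, x, x, x, cfg_clip, 0.0, 0.0), [0.25, -0.25]
        )


class TestMajorityVote:
    def test_printed_arrhythmia_subsets(self):
        assert len(ARRHYTHMIA_SUBSET_HARMONY) == 22
        assert len(ARRHYTHMIA_SUBSET_BEST_FIRST) == 25
        assert len(ARRHYTHMIA_SUBSET_PSO) == 37
        vote = majority_vote(
            ARRHYTHMIA_SUBSET_HARMONY,
            ARRHYTHMIA_SUBSET_BEST_FIRST,
            ARRHYTHMIA_SUBSET_PSO,
        )
        assert "DK" in vote  # present in all three subsets
        # independent hand set arithmetic: the union of pairwise intersections
        hand = (
            (ARRHYTHMIA_SUBSET_HARMONY & ARRHYTHMIA_SUBSET_BEST_FIRST)
            | (ARRHYTHMIA_SUBSET_HARMONY & ARRHYTHMIA_SUBSET_PSO)
            | (ARRHYTHMIA_SUBSET_BEST_FIRST & ARRHYTHMIA_SUBSET_PSO)
        )
        assert vote == hand
        # the vote yields the 16 consensus features as printed plus
        # t_interval, which appears in both the Best-First and PSO subsets
        assert vote == ARRHYTHMIA_SUBSET_CONSENSUS_PRINTED | {"t_interval"}
        assert len(vote) == 17

    def test_disjoint_sets_vote_empty(self):
        assert majority_vote({"a"}, {"b"}, {"c"}) == frozenset()

    @given(
        st.sets(st.sampled_from("abcdefgh")),
        st.sets(st.sampled_from("abcdefgh")),
        st.sets(st.sampled_from("abcdefgh")),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_idempotence(self, f1, f2, f3):
        v = majority_vote(f1, f2, f3)
        assert v == majority_vote(f3, f1, f2) == majority_vote(f2, f3, f1)
        assert majority_vote(f1, f1, f1) == frozenset(f1)
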