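"""The constrained evolutionary engine: selection, variation, sorting."""

import math

import numpy as np
import pytest

from pamod.graph import is_connected
from pamod.moea import (
    Individual,
    ParetoResult,
    SearchConfig,
    binary_tournament,
    clearing,
    crowding_distance,
    evolve,
    extreme_points,
    fast_nondominated_sort,
    initialize,
    knee_point,
    mutate,
    single_point_crossover,
)
from pamod.objectives import GeneSetCollection, ObjectiveVector, PathwayIndex
from pamod.synth import SyntheticSpec, generate

from conftest import make_net


def ind_from_objectives(s_a, r_a, feasible=True, n=4):
    ind = Individual(selection=np.zeros(n, dtype=bool))
    ind.objectives = ObjectiveVector(s_a=s_a, r_a=r_a)
    ind.feasible = feasible
    return ind


@pytest.fixture
def star_net():
    """Star with a high-scoring centre and positive leaves."""
    return make_net(
        [("hub", leaf) for leaf in ("l1", "l2", "l3")],
        scores={"hub": 5.0, "l1": 1.0, "l2": 0.5, "l3": 0.2},
    )


@pytest.fixture(scope="module")
def small_dataset():
    ds = generate(SyntheticSpec(n_nodes=60, planted_module_size=10, rng_seed=5))
    from pamod.bum import ScoringScheme, fit_bum

    fit = fit_bum(ds.network.pvalues)
    ds.network.assign_scores(ScoringScheme.from_fit(fit, 0.05))
    return ds


class TestInitialize:
    def test_star_becomes_whole_module(self, star_net):
        pop = initialize(star_net, SearchConfig(population_size=2))
        # hub is top seed; its positive leaves all join
        assert star_net.genes_of(pop[0].selection) == ["hub", "l1", "l2", "l3"]

    def test_population_capped_by_network_size(self, star_net):
        pop = initialize(star_net, SearchConfig(population_size=50))
        assert len(pop) == star_net.n_nodes

    def test_seeds_match_topk_sort(self, small_dataset):
        net = small_dataset.network
        cfg = SearchConfig(population_size=10)
        pop = initialize(net, cfg)
        expected = sorted(
            range(net.n_nodes), key=lambda i: (-net.scores[i], net.node_order[i])
        )[:10]
        for ind, seed in zip(pop, expected):
            assert ind.selection[seed]

    def test_initial_modules_connected(self, small_dataset):
        net = small_dataset.network
        for ind in initialize(net, SearchConfig(population_size=20)):
            assert is_connected(net, ind.selection)

    def test_error_without_positive_scores(self, star_net):
        star_net.scores = -np.ones(4)
        with pytest.raises(ValueError, match="alpha"):
            initialize(star_net, SearchConfig())


class TestTournament:
    def test_feasible_always_beats_infeasible(self):
        from pamod.moea import _tournament_winner

        rng = np.random.default_rng(0)
        good = ind_from_objectives(1.0, 1, feasible=True)
        good.rank, good.crowding = 5, 0.0
        bad = ind_from_objectives(100.0, 10, feasible=False)
        bad.rank, bad.crowding = 0, math.inf
        for _ in range(20):
            assert _tournament_winner(good, bad, rng) is good
            assert _tournament_winner(bad, good, rng) is good

    def test_crowding_breaks_rank_ties(self):
        from pamod.moea import _tournament_winner

        rng = np.random.default_rng(1)
        a = ind_from_objectives(1.0, 1)
        b = ind_from_objectives(2.0, 0)
        a.rank = b.rank = 0
        a.crowding, b.crowding = math.inf, 0.3
        for _ in range(20):
            assert _tournament_winner(a, b, rng) is a
            assert _tournament_winner(b, a, rng) is a

    def test_win_frequencies_match_binomial(self):
        """A strictly better individual wins whenever drawn: expected win
        rate 3/4 when two individuals are sampled with replacement."""
        rng = np.random.default_rng(12345)
        a = ind_from_objectives(1.0, 1)
        b = ind_from_objectives(0.5, 0)
        a.rank, b.rank = 0, 1
        a.selection = np.array([True, False])
        b.selection = np.array([False, True])
        wins = 0
        for _ in range(100):
            pool = binary_tournament([a, b], rng)
            wins += sum(1 for w in pool if w is a)
        n = 100 * 2
        p = 0.75
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(wins - n * p) <= 3 * sigma

    def test_skipped_when_population_converged(self):
        rng = np.random.default_rng(2)
        sel = np.array([True, False])
        pop = [Individual(selection=sel.copy()) for _ in range(4)]
        pool = binary_tournament(pop, rng, skip_dup_fraction=0.5)
        assert pool == pop  # whole population reproduces, in order


class TestCrossover:
    def test_identical_parents_identical_offspring(self):
        rng = np.random.default_rng(3)
        sel = np.array([True, False, True, False, True])
        p = Individual(selection=sel)
        c1, c2 = single_point_crossover(p, Individual(selection=sel.copy()), rng)
        assert np.array_equal(c1.selection, sel)
        assert np.array_equal(c2.selection, sel)

    def test_bit_conservation(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            p1 = Individual(selection=rng.random(20) < 0.4)
            p2 = Individual(selection=rng.random(20) < 0.4)
            c1, c2 = single_point_crossover(p1, p2, rng)
            assert np.array_equal(
                c1.selection.astype(int) + c2.selection.astype(int),
                p1.selection.astype(int) + p2.selection.astype(int),
            )

    def test_offspring_are_prefix_suffix_swaps(self):
        rng = np.random.default_rng(5)
        p1 = Individual(selection=np.array([True] * 6))
        p2 = Individual(selection=np.array([False] * 6))
        c1, c2 = single_point_crossover(p1, p2, rng)
        cut = int(c1.selection.sum())  # prefix of ones from p1
        assert 1 <= cut <= 5
        assert np.all(c1.selection[:cut]) and not np.any(c1.selection[cut:])
        assert not np.any(c2.selection[:cut]) and np.all(c2.selection[cut:])


class TestMutate:
    def test_no_eligible_neighbors_unchanged(self):
        net = make_net([("a", "b"), ("b", "c")],
                       scores={"a": 1.0, "b": -1.0, "c": -1.0})
        index = PathwayIndex(GeneSetCollection({"pw": ["zzz"]}), net)
        rng = np.random.default_rng(6)
        ind = Individual(selection=net.selection_of(["a"]))
        out = mutate(ind, net, index, rng)
        assert np.array_equal(out.selection, ind.selection)

    def test_addition_only_and_adjacency(self, small_dataset):
        net = small_dataset.network
        index = PathwayIndex(small_dataset.collection, net)
        rng = np.random.default_rng(7)
        for _ in range(500):
            start = int(rng.integers(net.n_nodes))
            sel = np.zeros(net.n_nodes, dtype=bool)
            sel[start] = True
            out = mutate(Individual(selection=sel), net, index, rng)
            added = np.flatnonzero(out.selection & ~sel)
            assert out.selection.sum() >= sel.sum()
            for j in added:
                assert j in net.neighbor_indices[start]

    def test_pathway_membership_qualifies_negative_neighbor(self):
        net = make_net([("a", "b")], scores={"a": 1.0, "b": -1.0})
        index = PathwayIndex(GeneSetCollection({"pw": ["b"]}), net)
        rng = np.random.default_rng(8)
        out = mutate(Individual(selection=net.selection_of(["a"])), net, index, rng)
        assert out.selection.all()

    def test_connectedness_preserved(self, small_dataset):
        net = small_dataset.network
        index = PathwayIndex(small_dataset.collection, net)
        rng = np.random.default_rng(9)
        sel = net.selection_of([net.node_order[0]])
        ind = Individual(selection=sel)
        for _ in range(30):
            ind = mutate(ind, net, index, rng)
            assert is_connected(net, ind.selection)


class TestClearing:
    def test_replicas_marked_infeasible(self):
        sel = np.array([True, False])
        pop = [Individual(selection=sel.copy(), feasible=True) for _ in range(5)]
        clearing(pop)
        assert [i.feasible for i in pop] == [True, False, False, False, False]

    def test_distinct_population_untouched(self):
        pop = [
            Individual(selection=np.eye(4, dtype=bool)[i], feasible=True)
            for i in range(4)
        ]
        clearing(pop)
        assert all(i.feasible for i in pop)

    def test_mixed_population_matches_pairwise_dedup(self):
        rng = np.random.default_rng(10)
        pop = [Individual(selection=rng.random(6) < 0.5, feasible=True)
               for _ in range(40)]
        clearing(pop)
        # brute force: an individual stays feasible iff no earlier twin
        for i, ind in enumerate(pop):
            has_earlier_twin = any(
                np.array_equal(pop[j].selection, ind.selection) for j in range(i)
            )
            assert ind.feasible == (not has_earlier_twin)


class TestSorting:
    def test_mutually_nondominated_single_front(self):
        pop = [ind_from_objectives(-1, -3), ind_from_objectives(-2, -2),
               ind_from_objectives(-3, -1)]
        fronts = fast_nondominated_sort(pop)
        assert len(fronts) == 1 and all(i.rank == 0 for i in pop)

    def test_chain_of_dominance(self):
        # maximisation scale: (2,2) dominates (1,1)
        a, b = ind_from_objectives(2, 2), ind_from_objectives(1, 1)
        fast_nondominated_sort([a, b])
        assert (a.rank, b.rank) == (0, 1)

    def test_infeasible_never_outranks_feasible(self):
        rng = np.random.default_rng(11)
        pop = [
            ind_from_objectives(rng.normal(), int(rng.integers(5)),
                                feasible=bool(rng.random() < 0.5))
            for _ in range(60)
        ]
        fast_nondominated_sort(pop)
        worst_feasible = max(i.rank for i in pop if i.feasible)
        best_infeasible = min((i.rank for i in pop if not i.feasible),
                              default=10**9)
        assert best_infeasible > worst_feasible

    def test_matches_pairwise_oracle(self):
        from pamod.moea import constrained_dominates

        rng = np.random.default_rng(12)
        for _ in range(10):
            pop = [ind_from_objectives(rng.normal(), int(rng.integers(4)))
                   for _ in range(50)]
            fast_nondominated_sort(pop)
            # peel fronts by exhaustive pairwise dominance
            remaining = list(pop)
            rank = 0
            while remaining:
                front = [p for p in remaining
                         if not any(constrained_dominates(q, p)
                                    for q in remaining if q is not p)]
                for p in front:
                    assert p.rank == rank
                remaining = [p for p in remaining if p not in front]
                rank += 1


class TestCrowding:
    def test_small_fronts_all_infinite(self):
        front = [ind_from_objectives(1, 2), ind_from_objectives(2, 1)]
        crowding_distance(front)
        assert all(i.crowding == math.inf for i in front)

    def test_equally_spaced_middle_gets_two(self):
        front = [ind_from_objectives(0, 2), ind_from_objectives(1, 1),
                 ind_from_objectives(2, 0)]
        crowding_distance(front)
        assert front[0].crowding == math.inf
        assert front[2].crowding == math.inf
        assert front[1].crowding == pytest.approx(2.0)

    def test_identical_vectors_interior_zero(self):
        front = [ind_from_objectives(1, 1) for _ in range(4)]
        crowding_distance(front)
        interior = [i for i in front if i.crowding != math.inf]
        assert interior and all(i.crowding == 0.0 for i in interior)


class TestEvolve:
    def run(self, ds, seed, gens=30):
        cfg = SearchConfig(population_size=16, generations=gens, rng_seed=seed)
        return evolve(ds.network, ds.collection, cfg)

    def test_same_seed_bit_identical(self, small_dataset):
        r1 = self.run(small_dataset, seed=42)
        r2 = self.run(small_dataset, seed=42)
        assert len(r1.front) == len(r2.front)
        for a, b in zip(r1.front, r2.front):
            assert np.array_equal(a.selection, b.selection)
            assert a.objectives == b.objectives
        assert r1.history == r2.history

    def test_front_connected_and_nondominated(self, small_dataset):
        from pamod.moea import constrained_dominates

        res = self.run(small_dataset, seed=1)
        assert res.front
        for ind in res.front:
            assert ind.feasible
            assert is_connected(small_dataset.network, ind.selection)
        for a in res.front:
            for b in res.front:
                if a is not b:
                    assert not constrained_dominates(a, b)

    def test_elitism_best_s_a_nondecreasing(self, small_dataset):
        res = self.run(small_dataset, seed=2, gens=40)
        best = [h["best_s_a"] for h in res.history]
        assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(best, best[1:]))

    def test_front_reevaluates_consistently(self, small_dataset):
        from pamod.objectives import evaluate

        res = self.run(small_dataset, seed=3)
        for ind in res.front:
            fresh = evaluate(small_dataset.network, small_dataset.collection,
                             ind.selection, res.config.r_ratio)
            assert fresh == ind.objectives


class TestFrontAnalysis:
    def make_result(self, objs):
        front = [ind_from_objectives(s, r) for s, r in objs]
        return ParetoResult(front=front, config=SearchConfig(),
                            history=[], node_order=[])

    def test_extremes(self):
        res = self.make_result([(10, 1), (5, 5), (1, 10)])
        i_s, i_r = extreme_points(res)
        assert (i_s, i_r) == (0, 2)

    def test_single_member_is_everything(self):
        res = self.make_result([(3, 3)])
        assert extreme_points(res) == (0, 0)
        assert knee_point(res) == 0

    def test_knee_is_the_bulge(self):
        # (9,9) sticks far out of the line joining (10,0) and (0,10)
        res = self.make_result([(10, 0), (9, 9), (0, 10)])
        assert knee_point(res) == 1

    def test_empty_front_errors(self):
        res = self.make_result([])
        with pytest.raises(ValueError):
            extreme_points(res)
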