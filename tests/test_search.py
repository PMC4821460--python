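"""Immune-search operators and the full optimization loop."""

import numpy as np
import pytest

from immunedag import (
    Antibody,
    Dag,
    ImmuneParams,
    ImmuneStructureLearner,
    K2Scorer,
    immune_search,
    enumerate_all_dags,
    is_acyclic,
    log_k2,
)
from immunedag.search import (
    clonal_select,
    construct_solution,
    crossover_step,
    init_population,
    mutate_step,
    suppress,
)

from conftest import make_dataset


class FakeRNG:
    """Replays a queue of integers through the Generator API mutate_step uses."""

    def __init__(self, values):
        self.values = list(values)

    def integers(self, *_args, **_kwargs):
        return self.values.pop(0)


class TestConstructSolution:
    def test_single_node_yields_empty_graph(self, rng):
        data = make_dataset([[1], [2], [1]], arity=[2])
        ab = construct_solution(K2Scorer(data), rng)
        assert ab.dag.arcs == frozenset()

    def test_perfect_copy_learns_one_arc(self, rng):
        copies = np.repeat(np.array([[1, 1], [2, 2]]), 250, axis=0)
        data = make_dataset(copies, arity=[2, 2])
        scorer = K2Scorer(data)
        ab = construct_solution(scorer, rng)
        assert len(ab.dag.arcs) == 1
        # either orientation scores identically and beats the empty graph
        assert ab.affinity > log_k2(Dag(2), data)
        assert log_k2(Dag(2, {(0, 1)}), data) == pytest.approx(
            log_k2(Dag(2, {(1, 0)}), data)
        )

    def test_ascent_contract(self, small_dataset, rng):
        scorer = K2Scorer(small_dataset)
        for _ in range(5):
            ab = construct_solution(scorer, rng)
            assert ab.affinity >= log_k2(Dag(3), small_dataset, scorer)


class TestInitPopulation:
    def test_sizes(self, small_dataset, rng):
        scorer = K2Scorer(small_dataset)
        params = ImmuneParams(n_pop=10, t_max=1, m_mem=8, seed=0)
        assert len(init_population([], scorer, params, rng)) == 10
        memory = [construct_solution(scorer, rng) for _ in range(7)]
        pop = init_population(memory, scorer, params, rng)
        assert len(pop) == 10
        assert [ab.dag for ab in pop[:7]] == [ab.dag for ab in memory]

    def test_seed_determinism(self, small_dataset):
        scorer = K2Scorer(small_dataset)
        params = ImmuneParams(n_pop=10, t_max=1, m_mem=5, seed=0)
        p1 = init_population([], scorer, params, np.random.default_rng(42))
        p2 = init_population([], scorer, params, np.random.default_rng(42))
        assert [ab.dag for ab in p1] == [ab.dag for ab in p2]


class TestClonalSelect:
    def _population(self, affinities):
        return [Antibody(Dag(2), a) for a in affinities]

    def test_selects_top_half_sorted_descending(self):
        pop = self._population([-5.0, -1.0, -3.0, -2.0])
        gs, gsc = clonal_select(pop, 0.5)
        assert [ab.affinity for ab in gs] == [-1.0, -2.0]
        assert [ab.affinity for ab in gsc] == [-1.0, -2.0]

    def test_floor_of_n_times_ps(self):
        pop = self._population(range(80))
        gs, gsc = clonal_select(pop, 0.5)
        assert len(gs) == len(gsc) == 40

    def test_ties_resolved_by_population_order(self):
        pop = self._population([-1.0] * 4)
        gs, _ = clonal_select(pop, 0.5)
        assert gs == [pop[0], pop[1]]

    def test_clones_are_independent_copies(self):
        pop = [Antibody(Dag(2, {(0, 1)}), -1.0), Antibody(Dag(2), -2.0)]
        gs, gsc = clonal_select(pop, 1.0)
        gsc[0] = Antibody(Dag(2), None)  # operators replace clone entries
        assert gs[0].dag.arcs == frozenset({(0, 1)})


class TestCrossover:
    def test_identical_parents_leave_gsc_unchanged(self, rng):
        gsc = [Antibody(Dag(2, {(0, 1)})), Antibody(Dag(2, {(0, 1)}))]
        assert crossover_step(gsc, rng) is False
        assert all(ab.dag.arcs == frozenset({(0, 1)}) for ab in gsc)

    def test_two_node_neighbourhood_swap(self, rng):
        gsc = [Antibody(Dag(2, {(0, 1)})), Antibody(Dag(2, {(1, 0)}))]
        assert crossover_step(gsc, rng) is True
        assert {gsc[0].dag.arcs, gsc[1].dag.arcs} == {
            frozenset({(0, 1)}),
            frozenset({(1, 0)}),
        }

    def test_offspring_always_acyclic(self, rng):
        gsc = [
            Antibody(Dag(4, {(0, 1), (1, 2)})),
            Antibody(Dag(4, {(2, 1), (1, 0), (0, 3)})),
            Antibody(Dag(4, {(3, 0), (3, 1), (3, 2)})),
        ]
        for _ in range(200):
            crossover_step(gsc, rng)
            for ab in gsc:
                assert is_acyclic(ab.dag.n_nodes, ab.dag.arcs)


class TestMutate:
    def test_deletion_of_single_arc_gives_empty_graph(self):
        gsc = [Antibody(Dag(2, {(0, 1)}), -1.0)]
        # antibody 0, strategy 1 (deletion), arc 0
        assert mutate_step(gsc, FakeRNG([0, 1, 0])) is True
        assert gsc[0].dag.arcs == frozenset()
        assert gsc[0].affinity is None  # stale score dropped

    def test_reversion(self):
        gsc = [Antibody(Dag(2, {(0, 1)}))]
        assert mutate_step(gsc, FakeRNG([0, 2, 0])) is True
        assert gsc[0].dag.arcs == frozenset({(1, 0)})

    def test_cycle_creating_addition_counts_but_changes_nothing(self):
        g = Dag(3, {(0, 1), (1, 2)})
        gsc = [Antibody(g)]
        # antibody 0, strategy 0 (addition), child j=0, pool [1, 2] -> pick 2
        assert mutate_step(gsc, FakeRNG([0, 0, 0, 1])) is False
        assert gsc[0].dag is g

    def test_random_stream_keeps_graphs_acyclic(self, rng):
        gsc = [Antibody(Dag(4, {(0, 1), (1, 2), (0, 3)}))]
        for _ in range(300):
            mutate_step(gsc, rng)
            assert is_acyclic(4, gsc[0].dag.arcs)


class TestSuppress:
    def test_distinct_affinities_pass_through(self):
        pop = [Antibody(Dag(2), a) for a in [-10.1, -12.3, -15.0]]
        assert suppress(pop) == pop

    def test_duplicates_keep_first(self):
        a = Antibody(Dag(2, {(0, 1)}), -5.0)
        b = Antibody(Dag(2, {(0, 1)}), -5.0)
        c = Antibody(Dag(2), -7.0)
        assert suppress([a, b, c]) == [a, c]

    def test_many_copies_collapse_to_one(self):
        copies = [Antibody(Dag(2), -3.0) for _ in range(6)]
        extras = [Antibody(Dag(2), -4.0), Antibody(Dag(2), -5.0)]
        assert len(suppress(copies + extras)) == 3


class TestImmuneSearch:
    def test_seed_determinism_bit_identical(self, small_dataset):
        params = ImmuneParams(n_pop=20, t_max=10, m_mem=15, seed=5)
        r1 = immune_search(small_dataset, params)
        r2 = immune_search(small_dataset, params)
        assert r1.best.dag == r2.best.dag
        assert np.array_equal(r1.trace, r2.trace)

    def test_reaches_exhaustive_optimum_on_three_nodes(self, small_dataset):
        scorer = K2Scorer(small_dataset)
        exhaustive = max(scorer.log_score(g) for g in enumerate_all_dags(3))
        res = immune_search(small_dataset, ImmuneParams(n_pop=20, t_max=30, m_mem=15, seed=1))
        assert res.best.affinity == pytest.approx(exhaustive, abs=1e-9)

    def test_trace_is_non_decreasing(self, small_dataset):
        res = immune_search(small_dataset, ImmuneParams(n_pop=20, t_max=15, m_mem=15, seed=2))
        assert np.all(np.diff(res.trace) >= 0)

    def test_param_validation(self, small_dataset):
        with pytest.raises(ValueError):
            ImmuneParams(n_pop=10, m_mem=10)
        with pytest.raises(ValueError):
            ImmuneParams(p_s=0.0)


class TestEstimator:
    def test_fit_exposes_sklearn_attributes(self, small_dataset):
        est = ImmuneStructureLearner(
            n_pop=20, n_iter=10, memory_size=15, random_state=0
        )
        est.fit(small_dataset.observations)
        assert est.n_features_in_ == 3
        assert is_acyclic(est.dag_.n_nodes, est.arcs_)
        assert est.trace_.shape == (10,)
        assert est.score_ == est.trace_[-1]

    def test_get_params_round_trip(self):
        from sklearn.base import clone

        est = ImmuneStructureLearner(n_pop=12, n_iter=3, memory_size=4)
        assert clone(est).get_params()["n_pop"] == 12

    def test_rejects_zero_based_codes(self):
        est = ImmuneStructureLearner(n_pop=4, n_iter=2, memory_size=2)
        with pytest.raises(ValueError):
            est.fit(np.zeros((5, 2), dtype=int))
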