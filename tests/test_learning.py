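import networkx as nx
import numpy as np
import pytest

from casgrn.cas import cas_all
from casgrn.datasets_io import DiscreteDataset
from casgrn.learning import (
    EdgeSpace,
    LocalStructure,
    cas_g,
    cas_l,
    exhaustive_search,
    full_edge_space,
    greedy_search,
    introduces_cycle,
    learn_local,
    merge_scored_edges,
    pool_local_edges,
)
from casgrn.scoring import total_score
from casgrn.synthetic import forward_sample, random_cpts, random_dag
from conftest import make_chain_bn, random_dataset


class TestIntroducesCycle:
    def test_three_cycle_detected(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        assert introduces_cycle(g, ("c", "a"))

    def test_branching_edge_allowed(self):
        g = nx.DiGraph([("a", "b")])
        g.add_node("c")
        assert not introduces_cycle(g, ("a", "c"))

    def test_self_loop_query_rejected(self):
        g = nx.DiGraph([("a", "b")])
        with pytest.raises(ValueError):
            introduces_cycle(g, ("a", "a"))

    def test_agreement_with_sort_and_verify_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(3, 8))
            names = [f"v{i}" for i in range(n)]
            g = random_dag(n, min(2.0, n - 1.0), n, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, dict(zip(sorted(g.nodes), names)))
            u, v = rng.choice(names, size=2, replace=False)
            if g.has_edge(u, v):
                continue
            trial = g.copy()
            trial.add_edge(u, v)
            assert introduces_cycle(g, (u, v)) == (
                not nx.is_directed_acyclic_graph(trial))


class TestGreedySearch:
    def test_independence_data_yields_empty_graph(self):
        rows = [[x, y] for x in (0, 1) for y in (0, 1) for _ in range(25)]
        d = DiscreteDataset(["a", "b"], [2, 2], np.array(rows))
        res = greedy_search(d, full_edge_space(["a", "b"]))
        assert res.graph.number_of_edges() == 0

    def test_chain_skeleton_recovered(self):
        bn = make_chain_bn(3, seed=2)
        d = forward_sample(bn, 2000, seed=3)
        res = greedy_search(d, full_edge_space(d.variable_names))
        skel = {frozenset(e) for e in res.graph.edges()}
        assert skel == {frozenset(("A", "B")), frozenset(("B", "C"))}

    def test_trace_deltas_positive_and_score_increasing(self):
        d = random_dataset(5, 300, seed=4)
        res = greedy_search(d, full_edge_space(d.variable_names))
        assert all(delta > 0 for _, delta, acc in res.trace if acc)
        # reported score matches from-scratch recomputation
        assert res.score == pytest.approx(total_score(d, res.graph), abs=1e-9)

    def test_returned_graph_acyclic(self):
        for s in range(10):
            d = random_dataset(5, 150, seed=100 + s)
            res = greedy_search(d, full_edge_space(d.variable_names))
            assert nx.is_directed_acyclic_graph(res.graph)


class TestExtendedMoves:
    def _misoriented_collider_data(self):
        # true structure a->c<-b with c lexicographically before b: add-only
        # greedy misorients its first edge at the exact score-equivalence tie
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, 2000)
        b = rng.integers(0, 2, 2000)
        c_col = np.where(rng.random(2000) < 0.95, a | b, 1 - (a | b))
        truth = nx.DiGraph([("a", "c"), ("b", "c")])
        return DiscreteDataset(
            ["a", "b", "c"], [2, 2, 2], np.column_stack([a, b, c_col])), truth

    def test_reverse_moves_recover_misoriented_collider(self):
        d, truth = self._misoriented_collider_data()
        add_only = greedy_search(d, full_edge_space(d.variable_names))
        extended = greedy_search(d, full_edge_space(d.variable_names),
                                 moves=("add", "delete", "reverse"))
        assert extended.score >= add_only.score
        assert set(extended.graph.edges()) == set(truth.edges())
        assert nx.is_directed_acyclic_graph(extended.graph)

    def test_default_moveset_is_add_only(self):
        d, _ = self._misoriented_collider_data()
        assert (greedy_search(d, full_edge_space(d.variable_names)).edges
                == greedy_search(d, full_edge_space(d.variable_names),
                                 moves=("add",)).edges)

    def test_unknown_move_rejected(self):
        d = random_dataset(3, 50, seed=70)
        with pytest.raises(ValueError):
            greedy_search(d, full_edge_space(d.variable_names), moves=("swap",))


class TestCasG:
    def test_space_never_exceeds_full(self):
        for s in range(5):
            d = random_dataset(6, 200, seed=20 + s)
            res = cas_g(d)
            n = d.n_variables
            assert res.space_size <= n * (n - 1)

    def test_restricted_space_never_examines_more_edges(self):
        d = random_dataset(8, 300, seed=26)
        cands = cas_all(d)
        restricted = EdgeSpace(cands.allowed_edges())
        assert len(restricted) <= len(full_edge_space(d.variable_names))

    def test_matches_exhaustive_on_tiny_instance(self):
        d = random_dataset(3, 1000, seed=27)
        g = cas_g(d)
        e = exhaustive_search(d)
        assert e.score >= g.score - 1e-9


class TestLearnLocal:
    def test_empty_candidates_empty_structure(self):
        d = random_dataset(4, 100, seed=30)
        local = learn_local(d, d.variable_names[0], set())
        assert local.scored_edges == []

    def test_collider_center_connects_all_neighbors(self, collider_data):
        local = learn_local(collider_data, "Z", {"X", "Y", "W"})
        touched = {u for (u, v), _ in local.scored_edges} | {
            v for (u, v), _ in local.scored_edges}
        assert touched == {"X", "Y", "W", "Z"}
        assert all("Z" in edge for edge, _ in local.scored_edges)

    def test_edge_count_bounded_by_candidates(self):
        d = random_dataset(6, 300, seed=31)
        v = d.variable_names[0]
        cands = set(d.variable_names[1:4])
        local = learn_local(d, v, cands)
        assert len(local.scored_edges) <= len(cands)

    def test_center_in_candidates_rejected(self):
        d = random_dataset(3, 50, seed=32)
        with pytest.raises(ValueError):
            learn_local(d, d.variable_names[0], {d.variable_names[0]})


class TestMergeAndPool:
    def test_cycle_closing_edge_rejected(self):
        pooled = {("a", "b"): 5.0, ("b", "c"): 4.0, ("c", "a"): 3.0}
        g, trace = merge_scored_edges(["a", "b", "c"], pooled)
        assert set(g.edges()) == {("a", "b"), ("b", "c")}
        assert [acc for _, _, acc in trace] == [True, True, False]

    def test_duplicate_edge_keeps_larger_delta(self):
        locals_ = [
            LocalStructure("a", [(("a", "b"), 2.0)]),
            LocalStructure("b", [(("a", "b"), 7.0)]),
        ]
        pooled = pool_local_edges(locals_)
        assert pooled == {("a", "b"): 7.0}

    def test_reverse_conflict_higher_delta_wins(self):
        pooled = {("a", "b"): 3.0, ("b", "a"): 5.0}
        g, _ = merge_scored_edges(["a", "b"], pooled)
        assert set(g.edges()) == {("b", "a")}


class TestCasL:
    def test_order_independence_over_nodes(self):
        """Per-node local structures pooled in any order give the same
        result (the searches are independent)."""
        d = random_dataset(6, 400, seed=40)
        cands = cas_all(d)
        from casgrn.scoring import ScoreCache
        locals_fwd = [learn_local(d, v, cands[v], 1.0, ScoreCache())
                      for v in d.variable_names]
        locals_rev = [learn_local(d, v, cands[v], 1.0, ScoreCache())
                      for v in reversed(d.variable_names)]
        assert pool_local_edges(locals_fwd) == pool_local_edges(locals_rev)

    def test_score_matches_recomputation(self):
        d = random_dataset(6, 300, seed=41)
        res = cas_l(d)
        assert res.score == pytest.approx(total_score(d, res.graph), abs=1e-9)
        assert nx.is_directed_acyclic_graph(res.graph)

    def test_chain_close_to_casg_quality(self):
        """Local learning tracks the global restricted search on chains."""
        from casgrn.evaluation import metrics, structure_confusion
        bn = make_chain_bn(5, seed=6)
        f_l, f_g = [], []
        for s in range(10):
            d = forward_sample(bn, 1000, seed=700 + s)
            for res, acc in ((cas_l(d), f_l), (cas_g(d), f_g)):
                rep = metrics(structure_confusion(bn.dag, res.graph, "skeleton"))
                acc.append(rep.f_score)
        assert np.mean(f_l) >= 0.8 * np.mean(f_g)


class TestExhaustiveSearch:
    def test_two_variable_enumeration(self):
        d = random_dataset(2, 300, seed=50)
        res = exhaustive_search(d)
        assert res.graph.number_of_edges() <= 1

    def test_refuses_more_than_four_variables(self):
        d = random_dataset(5, 50, seed=51)
        with pytest.raises(ValueError):
            exhaustive_search(d)

    def test_upper_bounds_all_learners(self):
        for s in range(5):
            d = random_dataset(4, 400, seed=60 + s)
            best = exhaustive_search(d).score
            assert best >= cas_g(d).score - 1e-9
            assert best >= cas_l(d).score - 1e-9
            assert best >= greedy_search(
                d, full_edge_space(d.variable_names)).score - 1e-9
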