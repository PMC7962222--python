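import itertools

import pytest

import rsmine as rm
from rsmine.ceis_enum import SearchState
from rsmine.graph_core import DataError, GraphSet
from rsmine.maximal_miner import identical_parent_shortcut, sibling_covered
from rsmine.synthetic import (
    GeneratorConfig,
    brute_force_frequent_and_maximal,
    planted_dataset,
    random_dataset,
)


def mine_ids(ds, smin, **flags):
    params = rm.MiningParams(min_support=smin, **flags)
    return {r.edge_ids for r in rm.mine_maximal(ds, params)}


class TestLocalMaximality:
    def test_toy_flags_exactly_the_two_maximal_subgraphs(self, toy):
        params = rm.MiningParams(min_support=3)
        frequent = list(rm.enumerate_frequent(toy, params))
        maximal_ids = mine_ids(toy, 3)
        for rec in frequent:
            # rebuild the search state for this edgeset and test locally
            order = sorted(
                rec.edge_ids,
                key=lambda e: (
                    rm.edge_distance(
                        toy.graph.edge(min(rec.edge_ids)), toy.graph.edge(e),
                        toy.graph, within=rec.edge_ids,
                    ),
                    e,
                ),
            )
            state = SearchState(toy.graph)
            state.init_root(order[0])
            for e in order[1:]:
                state.push(e)
            got = rm.local_maximality(state, rec.support, toy, params)
            assert got == (rec.edge_ids in maximal_ids)

    def test_full_support_neighbor_blocks_maximality(self):
        # edge (b,c) present in all graphs: {(a,b)} can always absorb it
        ds = rm.build_summary_graph(
            [[("a", "b"), ("b", "c")], [("a", "b"), ("b", "c")], [("b", "c")]]
        )
        state = SearchState(ds.graph)
        state.init_root(ds.graph.edge_by_labels("a", "b").id)
        sup = ds.attr(ds.graph.edge_by_labels("a", "b").id)
        assert not rm.local_maximality(state, sup, ds, rm.MiningParams(min_support=2))


class TestPruningPredicates:
    def test_sibling_covered_subset_semantics(self):
        a = GraphSet([1, 2, 3], 4)
        b = GraphSet([1, 2], 4)
        c = GraphSet([3, 4], 4)
        assert sibling_covered(b, [a])
        assert sibling_covered(a, [a])
        assert not sibling_covered(c, [a, b])
        assert not sibling_covered(a, [])

    def test_identical_parent_shortcut_is_equality(self):
        a = GraphSet([1, 2, 3], 4)
        assert identical_parent_shortcut(a, GraphSet([1, 2, 3], 4))
        assert not identical_parent_shortcut(a, GraphSet([1, 2], 4))

    def test_toy_sibling_pruning_example(self, toy):
        # at {(A,B)}, the child adding (B,C) has the same support {1,2,3}
        # as the earlier child adding (A,C): the (B,C) branch is covered
        ab = toy.graph.edge_by_labels("A", "B")
        ac = toy.graph.edge_by_labels("A", "C")
        bc = toy.graph.edge_by_labels("B", "C")
        sup_ac = rm.support_of([ab, ac], toy)
        sup_bc = rm.support_of([ab, bc], toy)
        assert sibling_covered(sup_bc, [sup_ac])

    def test_toy_identical_parent_example(self, toy):
        ab = toy.graph.edge_by_labels("A", "B")
        ac = toy.graph.edge_by_labels("A", "C")
        bc = toy.graph.edge_by_labels("B", "C")
        parent = rm.support_of([ab, ac], toy)
        child = rm.support_of([ab, ac, bc], toy)
        assert identical_parent_shortcut(parent, child)


class TestLevelOneRoots:
    def test_toy_roots_pruned_by_smaller_covering_neighbor(self, toy):
        roots = {
            toy.graph.format_edge(e.id)
            for e in rm.level_one_roots(toy, rm.MiningParams(min_support=3))
        }
        # every other edge's graph set is contained in a smaller adjacent edge's
        assert "A--B" in roots
        assert {"A--C", "A--D", "B--C", "B--D"}.isdisjoint(roots)

    def test_disjoint_supports_keep_all_roots(self):
        ds = rm.build_summary_graph([[("a", "b")], [("b", "c")]])
        roots = rm.level_one_roots(ds, rm.MiningParams(min_support=1))
        assert len(roots) == 2

    def test_equal_supports_prune_larger_id(self):
        ds = rm.build_summary_graph([[("a", "b"), ("b", "c")]] * 2)
        roots = rm.level_one_roots(ds, rm.MiningParams(min_support=2))
        assert [ds.graph.format_edge(e.id) for e in roots] == ["a--b"]


class TestMineMaximal:
    def test_toy_exactly_two_maximal(self, toy):
        got = {
            toy.graph.format_edgeset(sorted(ids)) for ids in mine_ids(toy, 3)
        }
        assert got == {"A--B;A--C;B--C;C--D", "A--B;A--D;B--D"}

    def test_single_connected_graph_smin1_returns_whole_graph(self):
        ds = rm.build_summary_graph(
            [[("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")]]
        )
        recs = rm.mine_maximal(ds, rm.MiningParams(min_support=1))
        assert len(recs) == 1
        assert recs[0].edge_ids == frozenset(e.id for e in ds.edges)

    def test_no_reported_subgraph_contains_another(self, toy):
        ids = list(mine_ids(toy, 3))
        for a, b in itertools.combinations(ids, 2):
            assert not (a <= b or b <= a)

    def test_oracle_equivalence_and_pruning_safety(self):
        """Maximal output equals the subset-lattice oracle on random datasets,
        is invariant under every pruning-rule on/off combination, and full
        pruning never explores more nodes than no pruning."""
        checked = 0
        seed = 1000
        while checked < 100:
            seed += 1
            cfg = GeneratorConfig(
                n_vertices=3 + seed % 8,
                n_graphs=2 + seed % 4,
                edge_prob=0.4,
                membership_prob=0.5,
                seed=seed,
            )
            ds = random_dataset(cfg)
            if ds.graph.n_edges > 12:
                continue
            for smin in range(1, min(ds.n_graphs, 5) + 1):
                _, oracle_m = brute_force_frequent_and_maximal(ds, smin)
                nodes = {}
                for r1, r2, r3 in itertools.product([True, False], repeat=3):
                    params = rm.MiningParams(
                        min_support=smin, rule1=r1, rule2=r2, rule3=r3
                    )
                    stats = rm.MiningStats()
                    out = rm.mine_maximal(ds, params, stats=stats)
                    assert {r.edge_ids for r in out} == oracle_m
                    nodes[(r1, r2, r3)] = stats.nodes_explored
                assert nodes[(True, True, True)] <= nodes[(False, False, False)]
            checked += 1

    def test_every_frequent_edgeset_is_covered(self, toy):
        """Completeness: each frequent edgeset is a subset of some reported
        maximal subgraph."""
        maximal = mine_ids(toy, 3)
        for r in rm.enumerate_frequent(toy, rm.MiningParams(min_support=3)):
            assert any(r.edge_ids <= m for m in maximal)

    def test_planted_motif_recovery(self):
        """A connected motif planted in exactly s_min graphs is reported with
        support exactly those graphs, across many seeds."""
        motif = [("v0", "v1"), ("v1", "v2"), ("v2", "v3"), ("v1", "v3")]
        for seed in range(50):
            cfg = GeneratorConfig(
                n_vertices=8, n_graphs=6, edge_prob=0.35,
                membership_prob=0.5, seed=seed,
            )
            s_min = 3
            ds = planted_dataset(motif, s_min, cfg)
            motif_ids = frozenset(
                ds.graph.edge_by_labels(a, b).id for a, b in motif
            )
            host = rm.support_of(motif_ids, ds)
            assert len(host) == s_min
            recs = rm.mine_maximal(ds, rm.MiningParams(min_support=s_min))
            hits = [r for r in recs if motif_ids <= r.edge_ids]
            assert len(hits) == 1
            assert hits[0].support == host


class TestSummarize:
    def test_triangle_density_one(self, toy):
        recs = [
            r
            for r in rm.mine_maximal(toy, rm.MiningParams(min_support=3))
            if r.n_edges == 3
        ]
        summary = rm.summarize_results(recs, min_edges=3)
        assert summary.n_filtered == 1
        assert summary.mean_density == pytest.approx(1.0)

    def test_path_density_half(self):
        ds = rm.build_summary_graph([[("a", "b"), ("b", "c"), ("c", "d")]])
        recs = rm.mine_maximal(ds, rm.MiningParams(min_support=1))
        summary = rm.summarize_results(recs, min_edges=3)
        assert summary.mean_edges == 3
        assert summary.mean_vertices == 4
        assert summary.mean_density == pytest.approx(0.5)

    def test_empty_list_all_zero(self):
        summary = rm.summarize_results([], min_edges=3)
        assert (summary.n_filtered, summary.mean_edges, summary.mean_density) == (0, 0.0, 0.0)

    def test_min_edges_validation(self):
        with pytest.raises(DataError):
            rm.summarize_results([], min_edges=0)
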