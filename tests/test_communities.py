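from __future__ import annotations

import json

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    bigclam_binary_oracle,
    exhaustive_best_modularity,
    matrix_modularity,
)
from psnstrat.communities import (
    Partition,
    bigclam,
    louvain,
    modularity,
    module_size_table,
)
from psnstrat.errors import CoverageError, ParameterError


def two_triangles() -> nx.Graph:
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def clique_pair(shared: bool) -> nx.Graph:
    g = nx.Graph()
    first = [0, 1, 2, 3]
    second = [3, 4, 5, 6] if shared else [4, 5, 6, 7]
    for clique in (first, second):
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                g.add_edge(u, v)
    return g


#: small graphs on which greedy modularity ascent reaches the global
#: optimum (verified against exhaustive search; an 8-cycle is a known
#: counterexample where the greedy pairs-partition is a local optimum)
SMALL_GRAPHS = {
    "two_triangles": two_triangles(),
    "matching6": nx.Graph([(0, 1), (2, 3), (4, 5)]),
    "path6": nx.path_graph(6),
    "complete5": nx.complete_graph(5),
    "star6": nx.star_graph(5),
    "barbell": nx.barbell_graph(3, 0),
    "cube": nx.hypercube_graph(3),
    "wheel5": nx.wheel_graph(5),
    "er8_a": nx.gnp_random_graph(8, 0.4, seed=1),
    "er8_b": nx.gnp_random_graph(8, 0.4, seed=2),
    "er7": nx.gnp_random_graph(7, 0.5, seed=3),
}
_weighted = nx.Graph()
for a, b in [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4)]:
    _weighted.add_edge(a, b, weight=2.0)
_weighted.add_edge(0, 4, weight=0.1)
SMALL_GRAPHS["two_squares_weighted"] = _weighted


class TestModularity:
    def test_single_module_is_exactly_zero(self):
        g = two_triangles()
        assert modularity(g, {n: 0 for n in g}) == 0.0

    def test_two_triangles_split_is_half(self):
        assignment = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(two_triangles(), assignment) == pytest.approx(0.5)

    def test_splitting_a_triangle_is_strictly_worse(self):
        g = two_triangles()
        best = exhaustive_best_modularity(g)
        assert best == pytest.approx(0.5)
        worse = {0: 0, 1: 0, 2: 2, 3: 1, 4: 1, 5: 1}
        assert modularity(g, worse) < 0.5

    def test_missing_node_raises_coverage_error(self):
        with pytest.raises(CoverageError):
            modularity(two_triangles(), {0: 0})

    def test_edgeless_network_raises(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(ParameterError):
            modularity(g, {1: 0, 2: 0})

    @pytest.mark.parametrize("name", sorted(SMALL_GRAPHS))
    def test_agrees_with_matrix_definition(self, name):
        g = SMALL_GRAPHS[name]
        rng = np.random.default_rng(42)
        nodes = list(g.nodes())
        for _ in range(5):
            assignment = {n: int(rng.integers(0, 3)) for n in nodes}
            assert modularity(g, assignment) == pytest.approx(
                matrix_modularity(g, assignment), abs=1e-12
            )


class TestLouvain:
    def test_two_triangles_recovered(self):
        partition = louvain(two_triangles(), seed=1)
        assert partition.n_modules == 2
        assert partition.modularity == pytest.approx(0.5)
        communities = {frozenset(c) for c in partition.communities()}
        assert communities == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_perfect_matching_gives_three_pairs(self):
        partition = louvain(nx.Graph([(0, 1), (2, 3), (4, 5)]), seed=2)
        assert sorted(partition.sizes()) == [2, 2, 2]

    @pytest.mark.parametrize("name", sorted(SMALL_GRAPHS))
    def test_reaches_exhaustive_optimum(self, name):
        g = SMALL_GRAPHS[name]
        partition = louvain(g, seed=11)
        assert partition.modularity == pytest.approx(
            exhaustive_best_modularity(g), abs=1e-9
        )

    @pytest.mark.parametrize("name", sorted(SMALL_GRAPHS))
    def test_reported_q_matches_recomputation(self, name):
        g = SMALL_GRAPHS[name]
        partition = louvain(g, seed=4)
        assert partition.modularity == pytest.approx(
            modularity(g, partition), abs=1e-9
        )

    def test_disconnected_components_give_nonnegative_q(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.path_graph(4))
        assert louvain(g, seed=0).modularity >= 0.0

    def test_seed_determinism_byte_for_byte(self):
        g = nx.gnp_random_graph(40, 0.15, seed=9)
        a = louvain(g, seed=123)
        b = louvain(g, seed=123)
        dump = lambda p: json.dumps(
            {str(k): v for k, v in p.assignment.items()}, sort_keys=True
        ) + repr(p.modularity)
        assert dump(a) == dump(b)

    def test_empty_network_raises(self):
        with pytest.raises(ParameterError):
            louvain(nx.Graph(), seed=0)

    def test_edgeless_network_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        partition = louvain(g, seed=0)
        assert partition.n_modules == 3
        assert partition.modularity == 0.0

    @given(st.integers(0, 10000))
    @settings(max_examples=15, deadline=None)
    def test_any_seed_reaches_triangle_optimum(self, seed):
        partition = louvain(two_triangles(), seed=seed)
        assert partition.modularity == pytest.approx(0.5)


class TestPartition:
    def test_contiguous_ids_enforced(self):
        with pytest.raises(ValueError):
            Partition({"a": 0, "b": 2}, 0.0, 2)

    def test_from_assignment_orders_by_size(self):
        partition = Partition.from_assignment(
            {"a": 7, "b": 7, "c": 7, "d": 5, "e": 5, "f": 9}
        )
        assert partition.assignment["a"] == 0
        assert partition.assignment["d"] == 1
        assert partition.assignment["f"] == 2


class TestBigClam:
    def test_disjoint_cliques_separated(self):
        cover = bigclam(clique_pair(shared=False), 2, seed=5)
        blocks = {}
        for node, comms in cover.memberships.items():
            assert len(comms) == 1
            blocks.setdefault(next(iter(comms)), set()).add(node)
        assert set(map(frozenset, blocks.values())) == {
            frozenset({0, 1, 2, 3}),
            frozenset({4, 5, 6, 7}),
        }

    def test_shared_node_gets_both_memberships(self):
        cover = bigclam(clique_pair(shared=True), 2, seed=5)
        doubles = [n for n, c in cover.memberships.items() if len(c) == 2]
        assert doubles == [3]

    def test_matches_binary_likelihood_oracle(self):
        g = clique_pair(shared=True)
        oracle_members, _ = bigclam_binary_oracle(g, 2)
        cover = bigclam(g, 2, seed=5)
        # community ids are exchangeable: compare the induced node blocks
        def blocks(members):
            out = {}
            for node, comms in members.items():
                for c in comms:
                    out.setdefault(c, set()).add(node)
            return set(map(frozenset, out.values()))

        assert blocks(cover.memberships) == blocks(oracle_members)

    def test_log_likelihood_trace_monotone(self):
        cover = bigclam(clique_pair(shared=True), 2, seed=9)
        trace = cover.ll_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_stationary_at_returned_optimum(self):
        from psnstrat.communities import _ascend

        g = clique_pair(shared=False)
        cover = bigclam(g, 2, seed=5)
        nodes = sorted(g.nodes(), key=str)
        index = {n: i for i, n in enumerate(nodes)}
        neighbors = [
            np.array(sorted(index[v] for v in g.neighbors(n)), dtype=int)
            for n in nodes
        ]
        edges = sorted(
            (min(index[u], index[v]), max(index[u], index[v]))
            for u, v in g.edges()
        )
        _, trace = _ascend(
            cover.strength.copy(), neighbors, edges,
            np.random.default_rng(0), max_iter=1, tol=0.0,
        )
        assert trace[-1] - trace[0] < 1e-4

    def test_threshold_formula(self):
        cover = bigclam(clique_pair(shared=False), 2, seed=1)
        assert cover.threshold == pytest.approx(
            float(np.sqrt(-np.log(1 - 1 / 8)))
        )

    def test_too_many_communities_rejected(self):
        with pytest.raises(ParameterError):
            bigclam(two_triangles(), 7, seed=0)

    def test_seed_determinism(self):
        g = clique_pair(shared=True)
        a = bigclam(g, 2, seed=33)
        b = bigclam(g, 2, seed=33)
        assert np.array_equal(a.strength, b.strength)
        assert a.memberships == b.memberships


class TestModuleSizeTable:
    def test_printed_share_arithmetic(self):
        # 860-node module inside a 4,418-node network -> 19.5%
        assignment = {}
        node = 0
        for module, size in enumerate([860, 818, 419, 2321]):
            for _ in range(size):
                assignment[f"n{node}"] = module
                node += 1
        partition = Partition(assignment, 0.0, 4)
        table = module_size_table(partition)
        assert table[0] == (3, 2321, 52.5)
        assert table[1] == (0, 860, 19.5)
        assert table[2] == (1, 818, 18.5)
        assert table[3] == (2, 419, 9.5)

    def test_single_module_is_hundred_percent(self):
        partition = Partition({"a": 0, "b": 0}, 0.0, 1)
        assert module_size_table(partition) == [(0, 2, 100.0)]

    def test_shares_sum_to_about_hundred(self):
        rng = np.random.default_rng(0)
        assignment = {f"n{i}": int(rng.integers(0, 7)) for i in range(300)}
        partition = Partition.from_assignment(assignment)
        table = module_size_table(partition)
        assert sum(s for _, _, s in table) == pytest.approx(100.0, abs=0.5)
        assert sorted((s for _, s, _ in table), reverse=True) == [
            s for _, s, _ in table
        ]
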