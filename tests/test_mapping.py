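"""Graph pruning, sequence selection and proportional distribution."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sketchlayout import (NoCoreError, bfs_double_sweep, choose_sequence, distribute,
                          find_cycle, prune, target_positions)
from sketchlayout.chain import Chain, Segment
from sketchlayout.mapping import _largest_remainder, _tau


def chain_of(lengths, closed=False):
    segs, x = [], 0.0
    for d in lengths:
        segs.append(Segment((x, 0.0), (x + d, 0.0)))
        x += d
    return Chain(segments=segs, closed=closed)


def brute_force_longest_cycle(g):
    """Oracle: exhaustive simple-cycle enumeration."""
    best = 0
    for cyc in nx.simple_cycles(g):
        best = max(best, len(cyc))
    return best


class TestPrune:
    def test_cycle_unchanged(self):
        g = prune(nx.cycle_graph(5))
        assert set(g.nodes) == set(range(5)) and g.number_of_edges() == 5

    def test_path_loses_ends(self):
        g = prune(nx.path_graph(["a", "b", "c", "d"]))
        assert set(g.nodes) == {"b", "c"}
        assert set(map(frozenset, g.edges)) == {frozenset(("b", "c"))}

    def test_star_keeps_center_only(self):
        g = prune(nx.star_graph(5))  # center 0, leaves 1..5
        assert set(g.nodes) == {0} and g.number_of_edges() == 0

    def test_no_core_raises(self):
        with pytest.raises(NoCoreError, match="multi-degree core"):
            prune(nx.Graph([("a", "b")]))

    def test_include_all_override(self):
        g = prune(nx.Graph([("a", "b")]), include_all=True)
        assert set(g.nodes) == {"a", "b"}

    def test_single_pass_not_iterative(self):
        # path a-b-c-d-e: single pass keeps b,c,d; iterative peeling would
        # erode further
        g = prune(nx.path_graph(5))
        assert set(g.nodes) == {1, 2, 3}

    def test_self_loops_dropped_with_warning(self):
        g = nx.cycle_graph(4)
        g.add_edge(0, 0)
        with pytest.warns(UserWarning, match="self-loop"):
            pruned = prune(g)
        assert nx.number_of_selfloops(pruned) == 0


class TestFindCycle:
    @pytest.mark.parametrize("n", [9, 12, 20, 35, 60])
    def test_cycle_graph_recovered_in_full(self, n):
        tau = _tau(n)
        seq = find_cycle(nx.cycle_graph(n), tau=tau, seed=0)
        assert seq is not None and len(seq) == n
        assert seq.kind == "cycle"
        assert seq.parent[seq.nodes[0]] == seq.nodes[-1]

    def test_tree_returns_none(self):
        g = nx.random_labeled_tree(30, seed=4)
        core = prune(g)
        assert find_cycle(core, tau=3, seed=0) is None

    def test_two_triangles_with_bridge_below_tau(self):
        # longest simple cycle is 3; tau = ceil(2*sqrt(6)) = 5 rejects it
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 3)])
        assert brute_force_longest_cycle(g) == 3
        assert find_cycle(g, tau=_tau(6), seed=0) is None

    def test_returned_cycle_is_valid_and_deterministic(self):
        g = nx.cycle_graph(15)
        g.add_edges_from([(0, 5), (3, 11)])
        a = find_cycle(g, tau=3, seed=42)
        b = find_cycle(g, tau=3, seed=42)
        assert a.nodes == b.nodes
        for u, v in zip(a.nodes, a.nodes[1:] + a.nodes[:1]):
            assert g.has_edge(u, v)
        assert len(set(a.nodes)) == len(a.nodes)

    def test_never_exceeds_bruteforce_on_small_graphs(self):
        """On exhaustively checked sparse graphs (<= 10 nodes), a returned
        heuristic cycle can never beat the true longest simple cycle."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(4, 11))
            g = nx.random_labeled_tree(n, seed=int(rng.integers(0, 10**6)))
            for _ in range(int(rng.integers(1, 4))):
                u, v = rng.integers(0, n, 2)
                if u != v:
                    g.add_edge(int(u), int(v))
            seq = find_cycle(g, tau=3, seed=0)
            if seq is not None:
                assert len(seq) <= brute_force_longest_cycle(g)

    def test_tau_floor(self):
        with pytest.raises(ValueError):
            find_cycle(nx.cycle_graph(5), tau=2)


class TestBfsDoubleSweep:
    def test_pruned_path(self):
        seq = bfs_double_sweep(prune(nx.path_graph(["a", "b", "c", "d"])), seed=0)
        assert set(seq.nodes) == {"b", "c"} and len(seq.nodes) == 2
        assert seq.parent[seq.nodes[1]] == seq.nodes[0]
        assert seq.parent[seq.nodes[0]] is None

    def test_cycle_respects_bfs_level_order(self):
        seq = bfs_double_sweep(nx.cycle_graph(4), seed=3)
        assert len(seq.nodes) == 4
        root = seq.nodes[0]
        dist = nx.single_source_shortest_path_length(nx.cycle_graph(4), root)
        levels = [dist[v] for v in seq.nodes]
        assert levels == sorted(levels)

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("x")
        seq = bfs_double_sweep(g, seed=0)
        assert seq.nodes == ["x"] and seq.parent["x"] is None

    def test_disconnected_maps_largest_component_with_warning(self):
        g = nx.disjoint_union(nx.cycle_graph(6), nx.cycle_graph(3))
        with pytest.warns(UserWarning, match="disconnected"):
            seq = bfs_double_sweep(g, seed=0)
        assert len(seq.nodes) == 6

    def test_farthest_start(self):
        # path core: the second sweep must start at an end of the path
        core = prune(nx.path_graph(10))  # nodes 1..8
        seq = bfs_double_sweep(core, seed=11)
        assert seq.nodes[0] in (1, 8)
        assert seq.nodes == list(range(1, 9)) or seq.nodes == list(range(8, 0, -1))


class TestDistribute:
    def test_worked_case_30_10_with_8(self):
        m = distribute(chain_of([30, 10]), _seq(8))
        assert m.counts == [6, 2]

    def test_largest_remainder_tie_break(self):
        m = distribute(chain_of([10, 10, 10]), _seq(10))
        assert m.counts == [4, 3, 3]

    def test_single_segment_gets_all(self):
        m = distribute(chain_of([17.3]), _seq(9))
        assert m.counts == [9]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(lengths=st.lists(st.floats(0.5, 100.0), min_size=1, max_size=12),
           total=st.integers(1, 200))
    def test_conservation_property(self, lengths, total):
        counts = _largest_remainder(lengths, total)
        assert sum(counts) == total
        assert all(c >= 0 for c in counts)

    def test_order_preserved(self):
        seq = _seq(11)
        m = distribute(chain_of([5, 25, 12]), seq)
        assert [v for ns in m.per_segment for v in ns] == seq.nodes


class TestChooseSequence:
    def test_cycle_for_closed_chain_on_cn(self):
        for n in (9, 20, 41):
            seq = choose_sequence(nx.cycle_graph(n), chain_closed=True, seed=0)
            assert seq.kind == "cycle" and len(seq) == n

    def test_tree_maps_as_path_even_for_closed_chain(self):
        core = prune(nx.random_labeled_tree(40, seed=2))
        seq = choose_sequence(core, chain_closed=True, seed=0)
        assert seq.kind == "path"

    def test_open_chain_never_uses_cycle(self):
        seq = choose_sequence(nx.cycle_graph(20), chain_closed=False, seed=0)
        assert seq.kind == "path"


class TestTargetPositions:
    def test_midpoint_for_single_node(self):
        chain = chain_of([10])
        m = distribute(chain, _seq(1))
        assert target_positions(chain, m) == {"v0": (5.0, 0.0)}

    def test_even_spacing_for_three(self):
        chain = chain_of([10])
        m = distribute(chain, _seq(3))
        xs = [target_positions(chain, m)[f"v{i}"][0] for i in range(3)]
        assert xs == pytest.approx([2.5, 5.0, 7.5])

    def test_closed_square_positions_on_perimeter(self):
        square = Chain(segments=[
            Segment((0, 0), (40, 0)), Segment((40, 0), (40, 40)),
            Segment((40, 40), (0, 40)), Segment((0, 40), (0, 0))], closed=True)
        m = distribute(square, _seq(8))
        for x, y in target_positions(square, m).values():
            on_edge = (y in (0.0, 40.0) and 0 <= x <= 40) or \
                      (x in (0.0, 40.0) and 0 <= y <= 40)
            assert on_edge


def _seq(k):
    from sketchlayout import NodeSequence
    nodes = [f"v{i}" for i in range(k)]
    parent = {v: nodes[i - 1] if i else None for i, v in enumerate(nodes)}
    return NodeSequence(nodes=nodes, kind="path", parent=parent)
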