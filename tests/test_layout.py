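"""Constrained embedder: projection, determinism, refinement, fidelity."""

import math

import networkx as nx
import numpy as np
import pytest

from sketchlayout import (AlignmentConstraint, ConstraintSet, LayoutParams,
                          RelativeConstraint, distribute, fidelity, layout, refine,
                          target_positions)
from sketchlayout.chain import Chain, Segment
from sketchlayout.mapping import NodeSequence

PARAMS = LayoutParams(iterations=120, seed=5)


def square_chain(side=200.0):
    return Chain(segments=[
        Segment((0.0, 0.0), (side, 0.0)), Segment((side, 0.0), (side, side)),
        Segment((side, side), (0.0, side)), Segment((0.0, side), (0.0, 0.0))],
        closed=True)


def cyclic_order_matches(positions, cycle_nodes):
    """Angular order around the centroid equals cycle order (up to rotation
    and direction)."""
    pts = np.array([positions[v] for v in cycle_nodes])
    ctr = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - ctr[1], pts[:, 0] - ctr[0])
    rank = np.argsort(ang)
    seq = list(rank)
    k = seq.index(0)
    fwd = seq[k:] + seq[:k]
    rev = [fwd[0]] + fwd[1:][::-1]
    return fwd == list(range(len(pts))) or rev == list(range(len(pts)))


class TestLayout:
    def test_single_relative_constraint(self):
        g = nx.Graph([("a", "b")])
        cs = ConstraintSet(relatives=[RelativeConstraint("horizontal", "a", "b")])
        anchors = {"a": (0.0, 0.0), "b": (30.0, 0.0)}
        res = layout(g, cs, anchors, PARAMS)
        assert res.positions["a"][0] <= res.positions["b"][0] - PARAMS.gap + 1e-6
        assert res.all_satisfied

    def test_alignment_projection_fixed_point(self):
        g = nx.path_graph(["a", "b", "c"])
        cs = ConstraintSet(alignments=[AlignmentConstraint("horizontal", ["a", "b", "c"])])
        anchors = {"a": (0.0, 3.0), "b": (40.0, 9.0), "c": (80.0, 1.0)}
        res = layout(g, cs, anchors, PARAMS)
        ys = [res.positions[v][1] for v in "abc"]
        assert max(ys) - min(ys) <= 1e-6

    def test_c12_on_square_chain(self):
        g = nx.cycle_graph(12)
        nodes = list(range(12))
        parent = {v: nodes[i - 1] for i, v in enumerate(nodes)}
        seq = NodeSequence(nodes=nodes, kind="cycle", parent=parent)
        chain = square_chain()
        mapping = distribute(chain, seq)
        anchors = target_positions(chain, mapping)
        from sketchlayout import classify, generate
        cs = generate(mapping, [classify(s) for s in chain.segments])
        res = layout(g, cs, anchors, PARAMS)
        assert res.all_satisfied and res.max_residual <= 1e-6
        assert cyclic_order_matches(res.positions, nodes)
        # refinement keeps the cyclic order
        refined = refine(g, res, PARAMS, constraints=cs)
        assert cyclic_order_matches(refined.positions, nodes)

    def test_deterministic_per_seed(self):
        g = nx.cycle_graph(8)
        cs = ConstraintSet(relatives=[RelativeConstraint("horizontal", 0, 1)])
        anchors = {0: (0.0, 0.0), 1: (50.0, 0.0)}
        r1 = layout(g, cs, anchors, LayoutParams(iterations=50, seed=9))
        r2 = layout(g, cs, anchors, LayoutParams(iterations=50, seed=9))
        assert r1.positions == r2.positions  # bit-identical
        r3 = layout(g, cs, anchors, LayoutParams(iterations=50, seed=10))
        assert r1.positions != r3.positions

    def test_unanchored_constraint_rejected(self):
        g = nx.Graph([("a", "b")])
        cs = ConstraintSet(relatives=[RelativeConstraint("horizontal", "a", "b")])
        with pytest.raises(ValueError, match="anchors"):
            layout(g, cs, {"a": (0.0, 0.0)}, PARAMS)

    def test_contradictory_cycle_rejected(self):
        g = nx.cycle_graph(3)
        cs = ConstraintSet(relatives=[RelativeConstraint("horizontal", 0, 1),
                                      RelativeConstraint("horizontal", 1, 2),
                                      RelativeConstraint("horizontal", 2, 0)])
        anchors = {v: (float(v), 0.0) for v in range(3)}
        with pytest.raises(ValueError, match="contradictory"):
            layout(g, cs, anchors, PARAMS)

    def test_degree_one_nodes_near_neighbour(self):
        g = nx.star_graph(4)  # hub 0
        g.add_edge(0, 99)
        cs = ConstraintSet()
        res = layout(g, cs, {0: (100.0, 100.0)}, LayoutParams(iterations=5, seed=1))
        # satellites initialize near the hub; after 5 gentle iterations they
        # are still within a few ideal edge lengths
        for v in (1, 2, 3, 4, 99):
            d = math.dist(res.positions[v], res.positions[0])
            assert d < 4 * 50.0


class TestRefine:
    def test_zero_iterations_is_identity(self):
        g = nx.path_graph(4)
        res = layout(g, ConstraintSet(), {0: (0.0, 0.0)}, PARAMS)
        params = LayoutParams(iterations=120, refine_iterations=0, seed=5)
        assert refine(g, res, params) is res

    def test_displacement_capped(self):
        g = nx.cycle_graph(10)
        params = LayoutParams(iterations=60, refine_iterations=25, seed=2)
        anchors = {v: (20.0 * v, 0.0) for v in g}
        res = layout(g, ConstraintSet(), anchors, params)
        refined = refine(g, res, params)
        for v in g:
            d = math.dist(res.positions[v], refined.positions[v])
            assert d <= params.refine_cap + 1e-9


class TestFidelity:
    def test_identity_scores_one(self):
        pts = {i: (float(i), float(i % 3)) for i in range(6)}
        assert fidelity(pts, pts) == pytest.approx(1.0)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(3)
        anchors = {i: tuple(p) for i, p in enumerate(rng.uniform(0, 100, (8, 2)))}
        th, s, t = 0.7, 2.5, np.array([30.0, -12.0])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = {i: tuple(s * rot @ np.array(p) + t) for i, p in anchors.items()}
        assert fidelity(moved, anchors) == pytest.approx(1.0, abs=1e-9)

    def test_random_scatter_scores_below_layout(self):
        g = nx.cycle_graph(12)
        nodes = list(range(12))
        seq = NodeSequence(nodes=nodes, kind="cycle",
                           parent={v: nodes[i - 1] for i, v in enumerate(nodes)})
        chain = square_chain()
        mapping = distribute(chain, seq)
        anchors = target_positions(chain, mapping)
        from sketchlayout import classify, generate
        cs = generate(mapping, [classify(s) for s in chain.segments])
        res = layout(g, cs, anchors, PARAMS)
        rng = np.random.default_rng(0)
        scatter = {v: tuple(rng.uniform(0, 200, 2)) for v in nodes}
        assert fidelity(scatter, anchors) < res.fidelity

    def test_too_few_shared_nodes(self):
        with pytest.raises(ValueError):
            fidelity({"a": (0.0, 0.0)}, {"a": (1.0, 1.0)})
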