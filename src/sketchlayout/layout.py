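"""Constrained force-directed layout with per-iteration constraint projection.

The embedder is a spring–repulsion model in the Fruchterman–Reingold family:
edges attract toward an ideal length, all node pairs repel, and per-node
displacement is capped by a linearly cooling temperature.  After each force
step the positions are projected onto the constraint set:

* each alignment group's members are set to their group mean on the
  alignment axis (horizontal groups share y, vertical groups share x);
* each violated relative constraint is repaired by moving both nodes
  symmetrically on its axis until their separation equals ``gap``.

Both projections are onto convex sets (a hyperplane, a half-space), so the
alternating sweeps converge to a feasible point whenever the constraint set
is consistent; a final projection loop after the last iteration drives every
residual below 1e-6.

Constrained nodes start at their sketch-derived anchors, degree-1 nodes at a
small random offset from their unique neighbour, and any remaining node at a
seeded random position, so the whole computation is deterministic for a
fixed seed.  A short unconstrained refinement pass (displacement-capped) can
then relax the slightly rigid constrained result.

Pairwise repulsion is exact up to ``exact_repulsion_limit`` nodes and
switches to a KD-tree neighbour list with a distance cutoff above it, keeping
the per-iteration cost near-linear at larger sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree, procrustes

from .constraints import ConstraintSet

logger = logging.getLogger(__name__)

__all__ = ["LayoutParams", "LayoutResult", "layout", "refine", "fidelity"]


@dataclass
class LayoutParams:
    """Force model and projection parameters.

    ideal_edge_length : px, spring rest length (also the repulsion scale).
    iterations        : constrained-phase iteration count.
    gap               : px, minimal separation enforced per relative constraint.
    refine_iterations : unconstrained refinement iterations (0 disables).
    refine_cap        : px, max total per-node displacement during refinement
                        (defaults to ideal_edge_length / 2).
    seed              : RNG seed for all random initialization.
    """

    ideal_edge_length: float = 50.0
    iterations: int = 500
    gap: float = 10.0
    refine_iterations: int = 30
    refine_cap: float | None = None
    seed: int = 0
    projection_sweeps: int = 10
    final_projection_sweeps: int = 2000
    exact_repulsion_limit: int = 1500
    repulsion_cutoff_factor: float = 3.0

    def __post_init__(self):
        if self.ideal_edge_length <= 0 or self.gap <= 0 or self.iterations <= 0:
            raise ValueError("ideal_edge_length, gap and iterations must be positive")
        if self.refine_iterations < 0:
            raise ValueError("refine_iterations must be >= 0")
        if self.refine_cap is None:
            self.refine_cap = self.ideal_edge_length / 2


@dataclass
class LayoutResult:
    """Final positions plus per-constraint satisfaction diagnostics."""

    positions: dict
    constraint_report: list
    fidelity: float | None
    anchors: dict = field(default_factory=dict)

    @property
    def all_satisfied(self) -> bool:
        return all(entry["satisfied"] for entry in self.constraint_report)

    @property
    def max_residual(self) -> float:
        return max((entry["residual"] for entry in self.constraint_report), default=0.0)


_AXIS_COL = {"horizontal": 0, "vertical": 1}  # relative constraints order x / y
# an alignment group on the "horizontal" axis shares the y coordinate
_ALIGN_COL = {"horizontal": 1, "vertical": 0}


def _compile_constraints(constraints: ConstraintSet, index: dict):
    rel = []
    seen = {"horizontal": set(), "vertical": set()}
    for c in constraints.relatives:
        pair = (c.first, c.second)
        if (c.second, c.first) in seen[c.axis]:
            raise ValueError(f"contradictory relative constraints on {c.axis} axis: {pair}")
        seen[c.axis].add(pair)
        rel.append((index[c.first], index[c.second], _AXIS_COL[c.axis]))
    align = [(np.array([index[v] for v in a.members]), _ALIGN_COL[a.axis])
             for a in constraints.alignments]
    return rel, align


def _topo_orders(rel):
    """Per-axis topological order of the relative-constraint DAG.

    Raises if the digraph is cyclic, i.e. the constraint set is infeasible —
    contradictions should have been filtered during generation.
    """
    import graphlib

    orders = {}
    for col in (0, 1):
        edges = [(a, b) for a, b, c in rel if c == col]
        ts = graphlib.TopologicalSorter()
        for a, b in edges:
            ts.add(b, a)  # b depends on a: a must come first
        try:
            order = list(ts.static_order())
        except graphlib.CycleError as exc:
            raise ValueError("contradictory relative constraints form a cycle; "
                             "they should have been filtered upstream") from exc
        preds = {}
        for a, b in edges:
            preds.setdefault(b, []).append(a)
        orders[col] = (order, preds)
    return orders


def _exact_relative_repair(pos, orders, gap):
    """Enforce every relative constraint exactly in one topological pass.

    Each node's coordinate is raised to max over predecessors + gap (nodes
    only move in the positive direction); the affected coordinate column is
    then re-centred so the pass introduces no net drift.
    """
    for col, (order, preds) in orders.items():
        if not order:
            continue
        idx = np.array(order)
        before = pos[idx, col].mean()
        for v in order:
            ps = preds.get(v)
            if ps:
                floor = max(pos[p, col] for p in ps) + gap
                if pos[v, col] < floor:
                    pos[v, col] = floor
        pos[idx, col] += before - pos[idx, col].mean()


def _project(pos: np.ndarray, rel, align, gap: float, sweeps: int, tol: float = 1e-9) -> float:
    """Alternating projection sweeps; returns the final max residual."""
    resid = np.inf
    for _ in range(sweeps):
        for idx, col in align:
            pos[idx, col] = pos[idx, col].mean()
        for a, b, col in rel:
            if pos[a, col] > pos[b, col] - gap:
                mid = (pos[a, col] + pos[b, col]) / 2
                pos[a, col] = mid - gap / 2
                pos[b, col] = mid + gap / 2
        resid = _max_residual(pos, rel, align, gap)
        if resid <= tol:
            break
    return resid


def _max_residual(pos, rel, align, gap) -> float:
    r = 0.0
    for idx, col in align:
        coords = pos[idx, col]
        r = max(r, float(coords.max() - coords.min()))
    for a, b, col in rel:
        r = max(r, float(pos[a, col] - (pos[b, col] - gap)))
    return r


def _repulsion(pos: np.ndarray, k: float, params: LayoutParams) -> np.ndarray:
    n = len(pos)
    if n <= 1:
        return np.zeros_like(pos)
    if n <= params.exact_repulsion_limit:
        diff = pos[:, None, :] - pos[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(d2, np.inf)
        d2 = np.maximum(d2, 1e-4)
        return ((k * k / d2)[:, :, None] * diff).sum(axis=1)
    cutoff = params.repulsion_cutoff_factor * k
    pairs = cKDTree(pos).query_pairs(r=cutoff, output_type="ndarray")
    disp = np.zeros_like(pos)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        diff = pos[i] - pos[j]
        d2 = np.maximum(np.einsum("ij,ij->i", diff, diff), 1e-4)
        f = (k * k / d2)[:, None] * diff
        np.add.at(disp, i, f)
        np.add.at(disp, j, -f)
    return disp


def _attraction(pos: np.ndarray, edges: np.ndarray, k: float) -> np.ndarray:
    disp = np.zeros_like(pos)
    if len(edges):
        i, j = edges[:, 0], edges[:, 1]
        diff = pos[j] - pos[i]
        d = np.maximum(np.linalg.norm(diff, axis=1), 1e-6)
        f = (d[:, None] / k) * diff  # magnitude d^2/k along the edge
        np.add.at(disp, i, f)
        np.add.at(disp, j, -f)
    return disp


def _capped_step(pos, disp, temp):
    norm = np.linalg.norm(disp, axis=1)
    scale = np.minimum(norm, temp) / np.maximum(norm, 1e-12)
    pos += disp * scale[:, None]


def _initial_positions(graph, nodes, index, anchors, params, bbox):
    rng = np.random.default_rng(params.seed)
    pos = np.full((len(nodes), 2), np.nan)
    for v, (x, y) in anchors.items():
        pos[index[v]] = (x, y)
    # satellites: degree-1 nodes hug their unique neighbour once it is placed
    changed = True
    while changed:
        changed = False
        for v in nodes:
            i = index[v]
            if not np.isnan(pos[i, 0]) or graph.degree(v) != 1:
                continue
            (u,) = graph.neighbors(v)
            j = index[u]
            if not np.isnan(pos[j, 0]):
                angle = rng.uniform(0, 2 * np.pi)
                r = params.ideal_edge_length * (0.25 + 0.5 * rng.uniform())
                pos[i] = pos[j] + r * np.array([np.cos(angle), np.sin(angle)])
                changed = True
    free = np.isnan(pos[:, 0])
    if free.any():
        (x0, y0), (x1, y1) = bbox
        pos[free, 0] = rng.uniform(x0, x1, free.sum())
        pos[free, 1] = rng.uniform(y0, y1, free.sum())
    return pos


def _report(constraints: ConstraintSet, pos, index, gap, tol=1e-6):
    report = []
    for c in constraints.relatives:
        col = _AXIS_COL[c.axis]
        residual = max(0.0, float(pos[index[c.first], col] - (pos[index[c.second], col] - gap)))
        report.append({"constraint": c, "satisfied": residual <= tol, "residual": residual})
    for a in constraints.alignments:
        col = _ALIGN_COL[a.axis]
        coords = pos[[index[v] for v in a.members], col]
        residual = float(coords.max() - coords.min())
        report.append({"constraint": a, "satisfied": residual <= tol, "residual": residual})
    return report


def layout(graph: nx.Graph, constraints: ConstraintSet, anchors: dict,
           params: LayoutParams | None = None) -> LayoutResult:
    """Run the constrained phase and return positions + diagnostics.

    ``anchors`` must cover every node referenced by a constraint; they seed
    the initial positions and later serve as the reference shape for the
    fidelity score.
    """
    params = params or LayoutParams()
    nodes = sorted(graph.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    for c in constraints.relatives:
        if c.first not in anchors or c.second not in anchors:
            raise ValueError("constraints reference nodes without anchors")
    rel, align = _compile_constraints(constraints, index)

    if anchors:
        pts = np.array(list(anchors.values()), dtype=float)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        pad = params.ideal_edge_length
        bbox = (lo - pad, hi + pad)
    else:
        bbox = (np.array([0.0, 0.0]), np.array([512.0, 512.0]))
    pos = _initial_positions(nx.Graph(graph), nodes, index, anchors, params, bbox)
    edges = np.array([[index[u], index[v]] for u, v in graph.edges() if u != v], dtype=int)
    k = params.ideal_edge_length

    t0, t1 = k / 2, 1.0
    for it in range(params.iterations):
        temp = t0 + (t1 - t0) * (it / max(params.iterations - 1, 1))
        disp = _repulsion(pos, k, params) + _attraction(pos, edges, k)
        if not np.isfinite(disp).all():
            raise FloatingPointError(f"non-finite forces at iteration {it}")
        _capped_step(pos, disp, temp)
        _project(pos, rel, align, params.gap, params.projection_sweeps)
    # final phase: alternate alignment averaging with an exact topological
    # repair of the relative DAG until every residual vanishes
    orders = _topo_orders(rel)
    resid = np.inf
    for _ in range(params.final_projection_sweeps):
        for idx, col in align:
            pos[idx, col] = pos[idx, col].mean()
        _exact_relative_repair(pos, orders, params.gap)
        resid = _max_residual(pos, rel, align, params.gap)
        if resid <= 1e-9:
            break
    if resid > 1e-6:
        logger.warning("constraint projection stalled at residual %.3g", resid)
    if not np.isfinite(pos).all():
        raise FloatingPointError("non-finite positions after constrained phase")

    positions = {v: (float(pos[index[v], 0]), float(pos[index[v], 1])) for v in nodes}
    fid = fidelity(positions, anchors) if len(anchors) >= 2 else None
    return LayoutResult(positions=positions,
                        constraint_report=_report(constraints, pos, index, params.gap),
                        fidelity=fid, anchors=dict(anchors))


def refine(graph: nx.Graph, result: LayoutResult, params: LayoutParams | None = None,
           constraints: ConstraintSet | None = None) -> LayoutResult:
    """Short unconstrained relaxation of a constrained result.

    Runs ``refine_iterations`` low-temperature force iterations with no
    projection; each node's total displacement from its constrained position
    is clamped to ``refine_cap``, so the sketch-imposed structure survives
    while locally cramped regions breathe.  With ``refine_iterations=0`` the
    result is returned unchanged.  If the generating ConstraintSet is passed,
    the satisfaction report is recomputed on the refined positions
    (refinement may violate constraints slightly; that is tolerated).
    """
    params = params or LayoutParams()
    if params.refine_iterations == 0:
        return result
    nodes = sorted(graph.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    pos = np.array([result.positions[v] for v in nodes], dtype=float)
    start = pos.copy()
    edges = np.array([[index[u], index[v]] for u, v in graph.edges() if u != v], dtype=int)
    k = params.ideal_edge_length
    cap = params.refine_cap

    t0, t1 = max(1.0, k / 10), 0.5
    for it in range(params.refine_iterations):
        temp = t0 + (t1 - t0) * (it / max(params.refine_iterations - 1, 1))
        disp = _repulsion(pos, k, params) + _attraction(pos, edges, k)
        if not np.isfinite(disp).all():
            raise FloatingPointError(f"non-finite forces at refinement iteration {it}")
        _capped_step(pos, disp, temp)
        # clamp cumulative displacement to the refinement cap
        total = pos - start
        norm = np.linalg.norm(total, axis=1)
        over = norm > cap
        if over.any():
            pos[over] = start[over] + total[over] * (cap / norm[over])[:, None]

    positions = {v: (float(pos[index[v], 0]), float(pos[index[v], 1])) for v in nodes}
    fid = fidelity(positions, result.anchors) if len(result.anchors) >= 2 else None
    report = (_report(constraints, pos, index, params.gap)
              if constraints is not None else result.constraint_report)
    return LayoutResult(positions=positions, constraint_report=report,
                        fidelity=fid, anchors=dict(result.anchors))


def fidelity(positions: dict, anchors: dict) -> float:
    """Similarity-invariant agreement between positions and anchors, in [0,1].

    Standardized Procrustes superimposition (translation, scaling, rotation
    and reflection) of the two point sets over their shared keys; the score
    is 1 minus the Procrustes disparity, clamped to [0,1].  Identical shapes
    up to a similarity transform score 1; an unrelated scatter scores near 0.
    """
    keys = sorted(set(positions) & set(anchors), key=str)
    if len(keys) < 2:
        raise ValueError("fidelity needs at least 2 shared nodes")
    a = np.array([positions[v] for v in keys], dtype=float)
    b = np.array([anchors[v] for v in keys], dtype=float)
    try:
        _, _, disparity = procrustes(a, b)
    except ValueError:
        # degenerate (zero-variance) configuration: no shape to compare
        return 0.0
    return float(np.clip(1.0 - disparity, 0.0, 1.0))
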