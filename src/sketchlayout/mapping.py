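"""Node-to-segment mapping.

The graph is first pruned to its multi-degree core V' = {v : deg(v) > 1}
(leaves contribute little to global shape and are left to the force model).
An ordered node sequence over V' is then chosen:

* if the sketch chain is closed, a DFS heuristic looks for a long simple
  cycle and accepts it when its length reaches the threshold
  tau = ceil(tau_factor * sqrt(|V'|));
* otherwise (open chain, or no sufficient cycle) a two-pass BFS "double
  sweep" orders the largest component starting from a far-out node, which
  approximates a diameter path of the graph.

Finally the sequence is apportioned over the chain's segments proportionally
to segment length (largest-remainder rounding) and provisional anchor
positions are placed evenly along each segment.
"""

from __future__ import annotations

import logging
import math
import random
import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .chain import Chain
from .errors import NoCoreError

logger = logging.getLogger(__name__)

__all__ = [
    "NodeSequence",
    "NodeLineMapping",
    "prune",
    "find_cycle",
    "bfs_double_sweep",
    "choose_sequence",
    "distribute",
    "target_positions",
]


@dataclass
class NodeSequence:
    """Ordered nodes with traversal-predecessor map.

    ``kind`` is "cycle" (parent of the first node is the last) or "path"
    (parent = BFS-tree parent; the root has parent ``None``).
    """

    nodes: list
    kind: str
    parent: dict

    def __len__(self):
        return len(self.nodes)


@dataclass
class NodeLineMapping:
    """Per-segment ordered node lists plus the traversal parent map."""

    per_segment: list
    parent: dict
    kind: str = "path"

    @property
    def counts(self):
        return [len(ns) for ns in self.per_segment]

    def node_segment_index(self) -> dict:
        return {v: i for i, ns in enumerate(self.per_segment) for v in ns}


def prune(graph: nx.Graph, include_all: bool = False) -> nx.Graph:
    """Restrict to nodes of degree > 1 (single pass on original degrees).

    Self-loops are dropped (with a warning) before degrees are computed.
    ``include_all=True`` keeps every node — the explicit fallback for graphs
    with no multi-degree core (e.g. stars of stars).

    Raises
    ------
    NoCoreError
        If V' would be empty and ``include_all`` is not set.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    g = nx.Graph(graph)  # undirected view for mapping
    loops = list(nx.selfloop_edges(g))
    if loops:
        warnings.warn(f"dropping {len(loops)} self-loop(s); self-loops are ignored in mapping")
        g.remove_edges_from(loops)
    if include_all:
        return g
    core = [v for v, d in g.degree() if d > 1]
    if not core:
        raise NoCoreError("graph has no multi-degree core")
    return g.subgraph(core).copy()


def _tau(n_core: int, tau_factor: float = 2.0) -> int:
    return max(3, math.ceil(tau_factor * math.sqrt(n_core)))


def find_cycle(pruned: nx.Graph, tau: int, seed: int = 0,
               work_cap_factor: int = 50):
    """DFS heuristic for a long simple cycle; ``None`` if none reaches ``tau``.

    DFS runs from each not-yet-visited node (seeded-shuffled order) and
    records the longest cycle closed by a back edge to the current DFS stack.
    Total work is capped at ``work_cap_factor * (|V| + |E|)`` traversal steps
    to keep the stage linear-time; exact longest-cycle search is NP-hard and
    out of scope.
    """
    if tau < 3:
        raise ValueError("tau must be >= 3")
    order = sorted(pruned.nodes, key=str)
    random.Random(seed).shuffle(order)
    nbrs = {v: sorted(pruned.neighbors(v), key=str) for v in order}
    visited: set = set()
    best: list = []
    budget = work_cap_factor * (pruned.number_of_nodes() + pruned.number_of_edges())

    for s in order:
        if s in visited or budget <= 0:
            continue
        stack = [s]
        index = {s: 0}
        iters = [iter(nbrs[s])]
        visited.add(s)
        while iters and budget > 0:
            budget -= 1
            try:
                w = next(iters[-1])
            except StopIteration:
                index.pop(stack.pop())
                iters.pop()
                continue
            u = stack[-1]
            if w in index:
                if len(stack) >= 2 and w != stack[-2]:  # back edge, not the tree edge
                    length = len(stack) - index[w]
                    if length > len(best):
                        best = stack[index[w]:]
            elif w not in visited:
                visited.add(w)
                index[w] = len(stack)
                stack.append(w)
                iters.append(iter(nbrs[w]))

    if len(best) < tau:
        return None
    # sanity: verify it is a simple graph cycle
    assert len(set(best)) == len(best)
    assert all(pruned.has_edge(a, b) for a, b in zip(best, best[1:] + best[:1]))
    parent = {v: best[i - 1] for i, v in enumerate(best)}
    return NodeSequence(nodes=list(best), kind="cycle", parent=parent)


def bfs_double_sweep(pruned: nx.Graph, seed: int = 0) -> NodeSequence:
    """Order the largest component by a two-pass BFS.

    The first BFS, from a seeded-random node, finds the farthest reachable
    node (ties broken by smallest id); the second BFS from that node yields
    the visit order and BFS-tree parents.  Nodes outside the largest
    component are excluded and reported via a warning.
    """
    if pruned.number_of_nodes() == 0:
        raise ValueError("pruned graph is empty")
    comps = sorted(nx.connected_components(pruned),
                   key=lambda c: (-len(c), min(str(v) for v in c)))
    comp = comps[0]
    if len(comps) > 1:
        left_out = pruned.number_of_nodes() - len(comp)
        warnings.warn(f"graph core is disconnected; {left_out} node(s) outside the "
                      "largest component are laid out unconstrained")
    nodes = sorted(comp, key=str)
    start = random.Random(seed).choice(nodes)
    dist = nx.single_source_shortest_path_length(pruned, start)
    v_far = min(dist, key=lambda v: (-dist[v], str(v)))
    # second sweep: deterministic BFS recording visit order and tree parents
    order, parent = [], {v_far: None}
    seen = {v_far}
    queue = deque([v_far])
    while queue:
        u = queue.popleft()
        order.append(u)
        for w in sorted(pruned.neighbors(u), key=str):
            if w not in seen:
                seen.add(w)
                parent[w] = u
                queue.append(w)
    return NodeSequence(nodes=order, kind="path", parent=parent)


def choose_sequence(pruned: nx.Graph, chain_closed: bool, tau_factor: float = 2.0,
                    seed: int = 0) -> NodeSequence:
    """Pick the mapping strategy: cycle for a closed chain when a long-enough
    cycle exists, else the BFS double sweep."""
    if chain_closed:
        seq = find_cycle(pruned, tau=_tau(pruned.number_of_nodes(), tau_factor), seed=seed)
        if seq is not None:
            logger.info("mapping kind: cycle (length %d)", len(seq))
            return seq
        logger.info("no sufficiently long cycle; falling back to BFS double sweep")
    seq = bfs_double_sweep(pruned, seed=seed)
    logger.info("mapping kind: path (%d nodes)", len(seq))
    return seq


def _largest_remainder(lengths, total: int) -> list:
    """Apportion ``total`` items proportionally to ``lengths``.

    Largest-remainder rounding; remainder ties go to the lower segment index.
    Guarantees the counts sum to ``total`` exactly.
    """
    d = sum(lengths)
    quotas = [li * total / d for li in lengths]
    counts = [math.floor(q) for q in quotas]
    short = total - sum(counts)
    by_remainder = sorted(range(len(lengths)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in by_remainder[:short]:
        counts[i] += 1
    return counts


def distribute(chain: Chain, seq: NodeSequence) -> NodeLineMapping:
    """Assign the sequence to chain segments proportionally to segment length.

    Segment i receives k_i = round(d_i * |seq| / D) nodes (largest-remainder
    rounding so that sum k_i = |seq|), taken from the sequence in traversal
    order so relative positions are maintained.
    """
    if not chain.segments or not seq.nodes:
        raise ValueError("distribute requires a non-empty chain and sequence")
    counts = _largest_remainder([s.length for s in chain.segments], len(seq.nodes))
    per_segment, at = [], 0
    for k in counts:
        per_segment.append(list(seq.nodes[at : at + k]))
        at += k
    return NodeLineMapping(per_segment=per_segment, parent=dict(seq.parent), kind=seq.kind)


def target_positions(chain: Chain, mapping: NodeLineMapping, canvas_scale: float = 1.0) -> dict:
    """Anchor the k_i nodes of segment i at even interior fractions
    j/(k_i + 1), j = 1..k_i, along the segment (scaled by ``canvas_scale``)."""
    if len(mapping.per_segment) != len(chain.segments):
        raise ValueError("mapping does not match chain")
    anchors = {}
    for seg, nodes in zip(chain.segments, mapping.per_segment):
        (x0, y0), (dx, dy) = seg.start, seg.delta
        k = len(nodes)
        for j, v in enumerate(nodes, start=1):
            t = j / (k + 1)
            anchors[v] = ((x0 + t * dx) * canvas_scale, (y0 + t * dy) * canvas_scale)
    return anchors
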