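"""Graph and layout I/O.

Graphs are read from GraphML or a whitespace/tab-delimited two-column edge
list (lines starting with ``#`` are comments; node ids are opaque strings).
Layouts are written as a positions JSON (node id -> [x, y]), optionally as
GraphML with coordinate attributes for downstream viewers, and optionally as
a simple SVG rendering of nodes and edges.  Layout space adopts image
coordinates (y down), and the SVG renderer keeps that convention so the
drawing matches the sketch without flipping.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .errors import GraphFormatError

__all__ = [
    "read_graph", "read_edge_list",
    "write_positions_json", "read_positions_json",
    "write_graphml_with_positions", "write_svg",
]


def read_edge_list(path) -> nx.Graph:
    """Parse a two-column edge list; ``#`` lines are skipped."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GraphFormatError(f"{path}: line {lineno}: expected two node ids, "
                                       f"got {line!r}")
            g.add_edge(parts[0], parts[1])
    if g.number_of_nodes() == 0:
        raise GraphFormatError(f"{path}: no edges found")
    return g


def read_graph(path) -> nx.Graph:
    """Read GraphML (by extension) or an edge list.

    A directed GraphML yields a DiGraph; the mapping stage treats it as
    undirected.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"graph file not found: {path}")
    if p.suffix.lower() in (".graphml", ".xml"):
        try:
            return nx.read_graphml(p)
        except Exception as exc:  # noqa: BLE001 - surface the file name
            raise GraphFormatError(f"{path}: not valid GraphML ({exc})") from exc
    return read_edge_list(p)


def write_positions_json(positions: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({str(v): [x, y] for v, (x, y) in positions.items()}, fh, indent=2)


def read_positions_json(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {v: (float(x), float(y)) for v, (x, y) in doc.items()}


def write_graphml_with_positions(graph: nx.Graph, positions: dict, path) -> None:
    g = graph.copy()
    for v, (x, y) in positions.items():
        g.nodes[v]["x"] = float(x)
        g.nodes[v]["y"] = float(y)
    nx.write_graphml(g, path)


def write_svg(graph: nx.Graph, positions: dict, path, node_radius: float = 4.0,
              margin: float = 20.0) -> None:
    """Minimal SVG rendering: grey edges under steel-blue nodes, y down."""
    xs = [p[0] for p in positions.values()]
    ys = [p[1] for p in positions.values()]
    x0, y0 = min(xs) - margin, min(ys) - margin
    w, h = max(xs) - x0 + margin, max(ys) - y0 + margin
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}" '
             f'viewBox="0 0 {w:.0f} {h:.0f}">']
    for u, v in graph.edges():
        if u in positions and v in positions:
            (xa, ya), (xb, yb) = positions[u], positions[v]
            parts.append(f'<line x1="{xa - x0:.1f}" y1="{ya - y0:.1f}" '
                         f'x2="{xb - x0:.1f}" y2="{yb - y0:.1f}" '
                         'stroke="#999" stroke-width="1"/>')
    for v, (x, y) in positions.items():
        parts.append(f'<circle cx="{x - x0:.1f}" cy="{y - y0:.1f}" r="{node_radius}" '
                     'fill="steelblue"/>')
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
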