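"""Synthetic sketches and graphs with known ground truth.

Everything the pipeline consumes can be generated programmatically: raster
sketches (line, L-shape, rectangle, circle, zigzag) rendered as dark strokes
on white with optional per-vertex jitter emulating freehand wobble, and
graphs (cycles, paths, trees, sparse random graphs) at any size.  All output
is deterministic per seed, so tests and the acceptance checks need no
external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from PIL import Image, ImageDraw

__all__ = ["SketchSpec", "render_sketch", "make_graph", "write_fixture"]

SHAPES = ("line", "L", "rectangle", "circle", "zigzag")


@dataclass(frozen=True)
class SketchSpec:
    """Recipe for a synthetic sketch.

    jitter is the standard deviation (px) of Gaussian per-vertex displacement
    applied before rasterization — the wobble that the slope threshold and
    simplification tolerance are designed to absorb.
    """

    shape: str
    stroke_width: int = 3
    jitter: float = 0.0
    resolution: tuple = (512, 512)
    seed: int = 0

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if self.stroke_width < 1:
            raise ValueError("stroke_width must be >= 1")


def _base_vertices(shape: str, w: int, h: int):
    """Ideal stroke vertices for each shape, plus whether the stroke closes."""
    if shape == "line":
        pts = [(0.1 * w, 0.5 * h), (0.9 * w, 0.5 * h)]
        closed = False
    elif shape == "L":
        pts = [(0.25 * w, 0.15 * h), (0.25 * w, 0.8 * h), (0.85 * w, 0.8 * h)]
        closed = False
    elif shape == "rectangle":
        pts = [(0.15 * w, 0.2 * h), (0.85 * w, 0.2 * h),
               (0.85 * w, 0.8 * h), (0.15 * w, 0.8 * h)]
        closed = True
    elif shape == "circle":
        cx, cy, r = 0.5 * w, 0.5 * h, 0.35 * min(w, h)
        theta = np.linspace(0, 2 * np.pi, 73)[:-1]
        pts = [(cx + r * np.cos(t), cy + r * np.sin(t)) for t in theta]
        closed = True
    else:  # zigzag
        pts = [(0.1 * w, 0.7 * h), (0.3 * w, 0.3 * h), (0.5 * w, 0.7 * h),
               (0.7 * w, 0.3 * h), (0.9 * w, 0.7 * h)]
        closed = False
    return [np.asarray(p, dtype=float) for p in pts], closed


def _densify(pts, closed, step=8.0):
    """Insert vertices every ~step px so jitter produces realistic wobble."""
    ring = pts + [pts[0]] if closed else pts
    out = []
    for a, b in zip(ring[:-1], ring[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
        for t in np.arange(n) / n:
            out.append(a + t * (b - a))
    if not closed:
        out.append(ring[-1])
    return out


def render_sketch(spec: SketchSpec):
    """Rasterize a sketch spec.

    Returns ``(image, truth)`` where ``image`` is a uint8 grayscale array
    (dark stroke on white) and ``truth`` is the ground-truth stroke polyline
    as an (n, 2) array of (x, y) vertices (closed shapes repeat the first
    vertex last) for downstream assertions.
    """
    w, h = spec.resolution
    pts, closed = _base_vertices(spec.shape, w, h)
    dense = _densify(pts, closed)
    rng = np.random.default_rng(spec.seed)
    if spec.jitter > 0:
        dense = [p + rng.normal(0.0, spec.jitter, 2) for p in dense]
    if closed:
        dense = dense + [dense[0]]
    img = Image.new("L", (w, h), 255)
    draw = ImageDraw.Draw(img)
    coords = [tuple(p) for p in dense]
    draw.line(coords, fill=0, width=spec.stroke_width, joint="curve")
    if spec.stroke_width >= 2:  # round caps/joints so corners stay connected
        r = spec.stroke_width / 2
        for p in coords:
            draw.ellipse([p[0] - r, p[1] - r, p[0] + r, p[1] + r], fill=0)
    truth = np.asarray(dense, dtype=float)
    return np.asarray(img, dtype=np.uint8), truth


def make_graph(kind: str, n: int, extra_edges: int = 0, seed: int = 0) -> nx.Graph:
    """Generate a test graph: cycle C_n, path P_n, a random labelled tree, or
    a sparse random graph (random tree + ``extra_edges`` distinct extra
    edges, hence connected with n-1+extra_edges edges)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "cycle":
        return nx.cycle_graph(n)
    if kind == "path":
        return nx.path_graph(n)
    if kind == "tree":
        return nx.random_labeled_tree(n, seed=seed)
    if kind == "sparse_random":
        g = nx.random_labeled_tree(n, seed=seed)
        rng = np.random.default_rng(seed)
        while g.number_of_edges() < n - 1 + extra_edges:
            u, v = rng.integers(0, n, 2)
            if u != v and not g.has_edge(int(u), int(v)):
                g.add_edge(int(u), int(v))
        return g
    raise ValueError(f"unknown graph kind {kind!r}")


def write_fixture(spec: SketchSpec, png_path, manifest_path=None):
    """Write a sketch PNG (and an optional JSON manifest with its ground
    truth) for manual inspection or external tools."""
    img, truth = render_sketch(spec)
    Image.fromarray(img).save(png_path)
    if manifest_path is not None:
        doc = {"spec": asdict(spec), "truth": truth.tolist()}
        with open(manifest_path, "w") as fh:
            json.dump(doc, fh)
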