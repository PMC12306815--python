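"""Polyline simplification and assembly into an ordered segment chain.

The skeleton tracer produces pixel-dense polylines.  These are compacted with
a radial-distance prefilter followed by Ramer–Douglas–Peucker, then merged and
ordered into a single chain of line segments whose consecutive endpoints
coincide exactly; a closed loop is detected when the two free ends meet within
a small offset threshold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import BranchingSketchError

logger = logging.getLogger(__name__)

__all__ = ["Segment", "Chain", "simplify_polyline", "build_chain", "point_polyline_distances"]


@dataclass(frozen=True)
class Segment:
    """A directed line segment between two (x, y) points, in pixels."""

    start: tuple
    end: tuple

    @property
    def length(self) -> float:
        return math.dist(self.start, self.end)

    @property
    def delta(self) -> tuple:
        return (self.end[0] - self.start[0], self.end[1] - self.start[1])


@dataclass
class Chain:
    """Ordered line segments with shared endpoints; ``closed`` if the last
    endpoint coincides with the first."""

    segments: list = field(default_factory=list)
    closed: bool = False

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    @property
    def points(self) -> np.ndarray:
        """Vertex sequence; for a closed chain the first vertex is repeated last."""
        pts = [self.segments[0].start] + [s.end for s in self.segments]
        return np.asarray(pts, dtype=float)

    def to_jsonl(self) -> str:
        """Debug dump: one JSON line per segment."""
        lines = [json.dumps({"start": list(s.start), "end": list(s.end)}) for s in self.segments]
        lines.append(json.dumps({"closed": self.closed, "total_length": self.total_length}))
        return "\n".join(lines)


def point_polyline_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each query point to a polyline (min over its segments)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(poly, dtype=float)
    if len(poly) == 1:
        return np.linalg.norm(points - poly[0], axis=1)
    a = poly[:-1]  # (m, 2)
    d = poly[1:] - a
    dd = np.einsum("ij,ij->i", d, d)
    dd[dd == 0] = 1.0
    # t: projection parameter of each point onto each segment, clipped to [0,1]
    t = np.clip(((points[:, None, :] - a[None]) * d[None]).sum(-1) / dd[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * d[None]
    return np.linalg.norm(points[:, None, :] - proj, axis=-1).min(axis=1)


def _perp_dist(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance of points to the segment a-b (endpoint-clamped)."""
    return point_polyline_distances(pts, np.vstack([a, b]))


def _radial_filter(pts: np.ndarray, tolerance: float) -> list:
    kept = [0]
    for i in range(1, len(pts) - 1):
        if math.dist(pts[i], pts[kept[-1]]) >= tolerance:
            kept.append(i)
    if len(pts) - 1 != kept[-1]:
        kept.append(len(pts) - 1)
    return kept


def _rdp(pts: np.ndarray, lo: int, hi: int, tolerance: float) -> set:
    """Iterative Ramer–Douglas–Peucker over ``pts[lo..hi]`` (original indices)."""
    keep = {lo, hi}
    stack = [(lo, hi)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        dists = _perp_dist(pts[a + 1 : b], pts[a], pts[b])
        j = int(np.argmax(dists))
        if dists[j] > tolerance:
            mid = a + 1 + j
            keep.add(mid)
            stack.append((a, mid))
            stack.append((mid, b))
    return keep


def simplify_polyline(poly: np.ndarray, tolerance: float,
                      high_quality: bool = True) -> np.ndarray:
    """Simplify a polyline, bounding every original point's deviation.

    By default Ramer–Douglas–Peucker runs on the full point sequence, so
    sharp corners survive exactly.  With ``high_quality=False`` a
    radial-distance pass (dropping points closer than ``tolerance`` to the
    previously kept point) decimates the polyline first and RDP runs on the
    survivors — faster on pixel-dense input, but the prefilter can hide a
    point from RDP's deviation test, so a final exhaustive check reinserts
    any original point that ends up farther than ``tolerance`` from the
    result.  Either way the bound

        max over original points of distance-to-simplified <= tolerance

    holds unconditionally, and the first and last points are preserved.
    """
    pts = np.asarray(poly, dtype=float)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline must contain at least 2 points")
    if high_quality:
        kept = sorted(_rdp(pts, 0, len(pts) - 1, tolerance))
    else:
        radial = _radial_filter(pts, tolerance)
        sub = pts[radial]
        kept = [radial[i] for i in sorted(_rdp(sub, 0, len(sub) - 1, tolerance))]
    # exhaustive guarantee: reinsert worst offenders until the bound holds
    while True:
        dists = point_polyline_distances(pts, pts[kept])
        worst = int(np.argmax(dists))
        if dists[worst] <= tolerance or worst in kept:
            break
        kept = sorted(set(kept) | {worst})
    out = pts[kept]
    # drop exact consecutive duplicates (invariant: consecutive points distinct)
    dedup = [0] + [i for i in range(1, len(out)) if not np.array_equal(out[i], out[i - 1])]
    return out[dedup]


def _assemble(polys: list, offset_threshold: float) -> tuple:
    """Greedy chain assembly; returns (vertex list, closed flag)."""
    pool = [list(map(tuple, np.asarray(p, dtype=float))) for p in polys]
    chain = pool.pop(0)
    while pool:
        best = None  # (dist, poly index, attach_at_end, reverse)
        for k, cand in enumerate(pool):
            for at_end in (True, False):
                chain_pt = chain[-1] if at_end else chain[0]
                for rev in (False, True):
                    c = cand[::-1] if rev else cand
                    cand_pt = c[0] if at_end else c[-1]
                    d = math.dist(chain_pt, cand_pt)
                    if best is None or d < best[0]:
                        best = (d, k, at_end, rev)
        d, k, at_end, rev = best
        if d >= offset_threshold:
            raise BranchingSketchError("branching or disconnected sketch")
        cand = pool.pop(k)
        if rev:
            cand = cand[::-1]
        if at_end:  # append: cand's head meets the chain's tail
            snap = tuple((a + b) / 2 for a, b in zip(chain[-1], cand[0]))
            chain[-1] = snap  # replaces both the old end and cand[0]
            chain.extend(cand[1:])
        else:  # prepend: cand's tail meets the chain's head
            snap = tuple((a + b) / 2 for a, b in zip(chain[0], cand[-1]))
            chain[0] = snap
            chain = cand[:-1] + chain
    closed = False
    if len(chain) > 2 and math.dist(chain[0], chain[-1]) <= offset_threshold:
        snap = tuple((a + b) / 2 for a, b in zip(chain[0], chain[-1]))
        chain[0] = chain[-1] = snap
        closed = True
    return chain, closed


def build_chain(polys: list, offset_threshold: float = 5.0) -> Chain:
    """Merge simplified polylines into one ordered chain of segments.

    Polylines are greedily concatenated (reversed where needed): at each step
    the polyline whose endpoint lies nearest (< ``offset_threshold``) to a
    free chain end is attached, the two endpoints snapped to their midpoint.
    The chain is closed when its final free ends also meet within the
    threshold.  Zero-length segments produced by snapping are dropped.

    Raises
    ------
    BranchingSketchError
        If the polylines cannot be ordered into a single open or closed
        chain ("branching or disconnected sketch").
    """
    if not polys:
        raise ValueError("build_chain requires at least one polyline")
    verts, closed = _assemble(polys, offset_threshold)
    segments = [Segment(a, b) for a, b in zip(verts[:-1], verts[1:]) if a != b]
    if not segments:
        raise ValueError("chain degenerated to a point after snapping")
    logger.debug("chain: %d segments, closed=%s, total length %.1f px",
                 len(segments), closed, sum(s.length for s in segments))
    return Chain(segments=segments, closed=closed)
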