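"""Sketch raster processing: binarization, thinning and polyline tracing.

A sketch arrives as a grayscale raster (dark strokes on a light background).
This module reduces it to its topological skeleton with the two-subiteration
Zhang–Suen thinning algorithm, then traces the one-pixel-wide skeleton into
ordered polylines.

Conventions
-----------
Images are ``numpy`` arrays indexed ``[row, col]``; all *point* coordinates
exposed by this module are ``(x, y) = (col, row)`` with the origin at the
top-left and y increasing downward.  Direction semantics downstream (e.g.
"top-to-bottom") inherit this convention.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import BlankSketchError

logger = logging.getLogger(__name__)

__all__ = [
    "load_image",
    "binarize",
    "remove_specks",
    "thin",
    "extract_polylines",
]


def load_image(path) -> np.ndarray:
    """Read a PNG (grayscale or RGB) as a uint8 grayscale array.

    RGB images are converted by luminance (PIL mode "L").
    """
    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=np.uint8)


def binarize(image: np.ndarray, threshold: float = 128, invert: bool = False) -> np.ndarray:
    """Threshold a grayscale image into a boolean foreground mask.

    Foreground is ``intensity < threshold`` (dark strokes on light paper);
    ``invert=True`` flips the polarity for light-on-dark sketches.  An image
    that is already binary (0/255) round-trips unchanged for any threshold
    strictly between its two levels.

    Raises
    ------
    BlankSketchError
        If no pixel falls below the threshold ("blank sketch").
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    arr = np.asarray(image)
    mask = (arr > threshold) if invert else (arr < threshold)
    if not mask.any():
        raise BlankSketchError("blank sketch")
    return mask


def remove_specks(mask: np.ndarray, min_size: int = 5) -> np.ndarray:
    """Drop 8-connected foreground components smaller than ``min_size`` pixels.

    A minimal noise guard for freehand input; pass ``min_size=0`` to disable.
    If every component is a speck the mask is returned unchanged (a tiny
    sketch beats an empty one).
    """
    if min_size <= 1:
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    if keep.size == 0:
        return mask
    return np.isin(labels, keep)


# Zhang-Suen neighbourhood: P2..P9 clockwise starting at north.
# With y down, "north" is row-1.
_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _neighbour_stack(img: np.ndarray) -> np.ndarray:
    """Stack of the 8 neighbour planes P2..P9 for every pixel."""
    p = np.pad(img, 1, constant_values=False)
    planes = [p[1 + dr : p.shape[0] - 1 + dr, 1 + dc : p.shape[1] - 1 + dc] for dr, dc in _OFFSETS]
    return np.stack(planes)


def thin(mask: np.ndarray) -> np.ndarray:
    """Zhang–Suen thinning iterated to its fixed point.

    Each pass runs the two subiterations: a foreground pixel is deleted when
    it has 2..6 foreground neighbours, exactly one 0->1 transition around the
    ring P2,P3,...,P9,P2, and satisfies the subiteration's two neighbour
    products (P2*P4*P6 = 0 and P4*P6*P8 = 0 in the first, P2*P4*P8 = 0 and
    P2*P6*P8 = 0 in the second).  Passes repeat until no pixel is deleted, so
    the result is idempotent by construction and preserves 8-connectivity.
    """
    img = np.ascontiguousarray(mask, dtype=bool)
    if not img.any():
        raise ValueError("thin requires a non-empty foreground")
    img = img.copy()
    while True:
        changed = False
        for sub in (0, 1):
            nb = _neighbour_stack(img)
            b = nb.sum(axis=0)
            ring = np.concatenate([nb, nb[:1]], axis=0)
            a = ((~ring[:-1]) & ring[1:]).sum(axis=0)
            p2, p4, p6, p8 = nb[0], nb[2], nb[4], nb[6]
            if sub == 0:
                c1 = ~(p2 & p4 & p6)
                c2 = ~(p4 & p6 & p8)
            else:
                c1 = ~(p2 & p4 & p8)
                c2 = ~(p2 & p6 & p8)
            delete = img & (b >= 2) & (b <= 6) & (a == 1) & c1 & c2
            if delete.any():
                img[delete] = False
                changed = True
        if not changed:
            return img


def _skeleton_adjacency(skel: np.ndarray) -> dict:
    """8-adjacency between skeleton pixels, with redundant diagonals dropped.

    A diagonal link is redundant when either orthogonal pixel between its two
    ends is itself on the skeleton; dropping it leaves connectivity intact and
    avoids tracing the same corner twice.
    """
    pixels = {(int(c), int(r)) for r, c in np.argwhere(skel)}
    adj: dict = {p: [] for p in pixels}
    for x, y in pixels:
        for dx, dy in ((1, 0), (0, 1), (1, 1), (1, -1)):
            q = (x + dx, y + dy)
            if q not in pixels:
                continue
            if dx and dy and (((x + dx, y) in pixels) or ((x, y + dy) in pixels)):
                continue
            adj[(x, y)].append(q)
            adj[q].append((x, y))
    return adj


def extract_polylines(skel: np.ndarray) -> list:
    """Trace a skeleton into polylines following 8-connected paths.

    Walks consume adjacency links exactly once, seeded first at skeleton
    endpoints (pixels with a single link), then at junction leftovers, and
    finally on pure cycles, so the union of the returned polylines covers the
    whole skeleton save isolated single pixels.  At a junction the walk
    continues along the link that best preserves its current heading;
    remaining branches are picked up by later walks.  Branching sketches are
    out of the method's intended scope, so encountering a junction emits a
    warning.

    Returns a list of ``(n, 2)`` float arrays of (x, y) points.  A skeleton of
    isolated pixels only yields an empty list with a warning instead of a
    crash.
    """
    if not np.asarray(skel).any():
        raise ValueError("extract_polylines requires a non-empty skeleton")
    adj = _skeleton_adjacency(np.asarray(skel, dtype=bool))
    degree = {p: len(nbrs) for p, nbrs in adj.items()}
    if all(d == 0 for d in degree.values()):
        warnings.warn("skeleton consists of isolated pixels only; no polylines extracted")
        return []
    if any(d >= 3 for d in degree.values()):
        warnings.warn("sketch skeleton contains branch points; branching sketches are "
                      "only handled best-effort")

    remaining = {p: list(nbrs) for p, nbrs in adj.items()}

    def _consume(a, b):
        remaining[a].remove(b)
        remaining[b].remove(a)

    def _pick_start():
        cands = [p for p, nbrs in remaining.items() if nbrs]
        if not cands:
            return None
        odd = [p for p in cands if len(remaining[p]) % 2 == 1]
        pool = odd if odd else cands
        # endpoints (single link) first, then deterministic order
        return min(pool, key=lambda p: (len(remaining[p]) != 1, p))

    polylines = []
    while True:
        start = _pick_start()
        if start is None:
            break
        path = [start]
        heading = None
        cur = start
        while remaining[cur]:
            nbrs = sorted(remaining[cur])
            if heading is None or len(nbrs) == 1:
                nxt = nbrs[0]
            else:
                nxt = max(nbrs, key=lambda q: (heading[0] * (q[0] - cur[0])
                                               + heading[1] * (q[1] - cur[1]), q))
            _consume(cur, nxt)
            heading = (nxt[0] - cur[0], nxt[1] - cur[1])
            path.append(nxt)
            cur = nxt
            if cur == start:
                break  # closed a cycle
        if len(path) >= 2:
            polylines.append(np.asarray(path, dtype=float))
    logger.debug("extracted %d polylines from %d skeleton pixels", len(polylines), len(adj))
    return polylines
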