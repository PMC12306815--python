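"""Direction classification and placement-constraint generation.

Each chain segment gets one of eight direction labels from its slope: nearly
horizontal (l-r / r-l), nearly vertical (t-b / b-t) or diagonal by sign pair
(tl-br, br-tl, tr-bl, bl-tr).  "Nearly" is controlled by the slope threshold
epsilon (default 0.2), which absorbs the wobble of freehand strokes.  Note
image coordinates have y growing downward, so dy > 0 means top-to-bottom.

From the node-line mapping, each node v with traversal predecessor q yields a
relative-placement constraint oriented by the label of v's segment (diagonal
labels yield one horizontal and one vertical constraint); each horizontal or
vertical segment holding two or more nodes additionally yields an alignment
group over its node sequence.

The resulting ConstraintSet serializes to the option schema of the fCoSE
constrained-layout engine (relativePlacementConstraint / alignmentConstraint)
so generated constraints can drive that ecosystem unchanged.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

from .chain import Segment
from .mapping import NodeLineMapping

logger = logging.getLogger(__name__)

__all__ = [
    "HORIZONTAL_LABELS", "VERTICAL_LABELS", "DIAGONAL_LABELS",
    "RelativeConstraint", "AlignmentConstraint", "ConstraintSet",
    "classify", "generate",
]

HORIZONTAL_LABELS = ("l-r", "r-l")
VERTICAL_LABELS = ("t-b", "b-t")
DIAGONAL_LABELS = ("tl-br", "br-tl", "tr-bl", "bl-tr")


@dataclass(frozen=True)
class RelativeConstraint:
    """Ordering of two nodes on one axis.

    ``axis="horizontal"``: ``first`` left of ``second``;
    ``axis="vertical"``: ``first`` above (top of) ``second``.
    """

    axis: str
    first: object
    second: object


@dataclass
class AlignmentConstraint:
    """Node group sharing a coordinate: ``horizontal`` groups share y (they
    lie on a horizontal line), ``vertical`` groups share x."""

    axis: str
    members: list


@dataclass
class ConstraintSet:
    relatives: list = field(default_factory=list)
    alignments: list = field(default_factory=list)

    def to_fcose_json(self) -> str:
        rel = []
        for c in self.relatives:
            if c.axis == "horizontal":
                rel.append({"left": c.first, "right": c.second})
            else:
                rel.append({"top": c.first, "bottom": c.second})
        align = {"horizontal": [], "vertical": []}
        for a in self.alignments:
            align[a.axis].append(list(a.members))
        return json.dumps({"relativePlacementConstraint": rel,
                           "alignmentConstraint": align}, indent=2)

    @classmethod
    def from_fcose_json(cls, text: str) -> "ConstraintSet":
        doc = json.loads(text)
        relatives = []
        for c in doc.get("relativePlacementConstraint", []):
            if "left" in c:
                relatives.append(RelativeConstraint("horizontal", c["left"], c["right"]))
            else:
                relatives.append(RelativeConstraint("vertical", c["top"], c["bottom"]))
        alignments = []
        for axis in ("horizontal", "vertical"):
            for grp in doc.get("alignmentConstraint", {}).get(axis, []):
                alignments.append(AlignmentConstraint(axis, list(grp)))
        return cls(relatives=relatives, alignments=alignments)


def classify(segment: Segment, epsilon: float = 0.2) -> str:
    """Label a segment's direction by its slope.

    The horizontal test |dy/dx| < epsilon runs first (dx = 0 fails it), then
    the vertical test |dx/dy| < epsilon; otherwise the label is diagonal by
    the sign pair of (dx, dy).  For epsilon < 1 the two axis tests are
    mutually exclusive (the product of the two ratios is 1).
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    dx, dy = segment.delta
    if dx == 0 and dy == 0:
        raise ValueError("cannot classify a zero-length segment")
    if dx != 0 and abs(dy / dx) < epsilon:
        return "l-r" if dx > 0 else "r-l"
    if dy != 0 and abs(dx / dy) < epsilon:
        return "t-b" if dy > 0 else "b-t"
    if dx > 0 and dy > 0:
        return "tl-br"
    if dx < 0 and dy < 0:
        return "br-tl"
    if dx < 0 and dy > 0:
        return "tr-bl"
    return "bl-tr"


def _pair_constraints(label: str, q, v) -> list:
    """Relative constraints for predecessor q -> node v under a segment label."""
    out = []
    if label in ("l-r", "tl-br", "bl-tr"):
        out.append(RelativeConstraint("horizontal", q, v))
    elif label in ("r-l", "br-tl", "tr-bl"):
        out.append(RelativeConstraint("horizontal", v, q))
    if label in ("t-b", "tl-br", "tr-bl"):
        out.append(RelativeConstraint("vertical", q, v))
    elif label in ("b-t", "br-tl", "bl-tr"):
        out.append(RelativeConstraint("vertical", v, q))
    return out


def generate(mapping: NodeLineMapping, labels: list) -> ConstraintSet:
    """Emit relative-placement and alignment constraints from a mapping.

    For each mapped node v with predecessor q = P(v), the label of v's
    segment orients one relative constraint (two for diagonal labels).  A
    constraint contradicting an earlier one (the reversed pair on the same
    axis — possible when a closed chain's labels fold back) is dropped with a
    warning, first-come-wins.  Horizontal/vertical segments with >= 2 nodes
    contribute an alignment group over their node sequence; groups are not
    merged across segments.
    """
    if len(labels) != len(mapping.per_segment):
        raise ValueError("labels must align one-to-one with mapping segments")
    cs = ConstraintSet()
    seen = {"horizontal": set(), "vertical": set()}
    succ = {"horizontal": {}, "vertical": {}}  # per-axis DAG for contradiction checks
    dropped = 0

    def _reaches(axis, src, dst):
        stack, visited = [src], set()
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            if u in visited:
                continue
            visited.add(u)
            stack.extend(succ[axis].get(u, ()))
        return False

    for nodes, label in zip(mapping.per_segment, labels):
        for v in nodes:
            q = mapping.parent.get(v)
            if q is None or q == v:
                continue
            for c in _pair_constraints(label, q, v):
                if (c.first, c.second) in seen[c.axis]:
                    continue  # exact duplicate
                # contradiction: the reverse ordering is already implied
                # (directly or through a chain of earlier constraints)
                if _reaches(c.axis, c.second, c.first):
                    dropped += 1
                    continue
                seen[c.axis].add((c.first, c.second))
                succ[c.axis].setdefault(c.first, []).append(c.second)
                cs.relatives.append(c)
        if len(nodes) >= 2 and label in HORIZONTAL_LABELS + VERTICAL_LABELS:
            axis = "horizontal" if label in HORIZONTAL_LABELS else "vertical"
            cs.alignments.append(AlignmentConstraint(axis, list(nodes)))
    if dropped:
        warnings.warn(f"dropped {dropped} contradictory relative constraint(s) "
                      "(closed chain folding back); keeping the earlier of each pair")
    logger.info("generated %d relative and %d alignment constraints",
                len(cs.relatives), len(cs.alignments))
    return cs
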