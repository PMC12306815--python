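"""The four-step sketch-to-layout pipeline.

1. line segment extraction — binarize, thin, trace, simplify, chain;
2. node-line mapping — prune, pick a cycle or BFS double-sweep order,
   apportion it over the chain;
3. constraint generation — classify segment directions, emit relative
   placement and alignment constraints;
4. constrained layout — force-directed with projection, then a short
   unconstrained refinement.

``run_pipeline`` works on in-memory objects; ``run_pipeline_files`` wraps it
with file I/O for the CLI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from . import image as img_mod
from .chain import Chain, build_chain, simplify_polyline
from .constraints import ConstraintSet, classify, generate
from .io import read_graph, write_graphml_with_positions, write_positions_json, write_svg
from .layout import LayoutParams, LayoutResult, layout as run_layout, refine
from .mapping import NodeLineMapping, choose_sequence, distribute, prune, target_positions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineRun", "extract_chain", "run_pipeline",
           "run_pipeline_files"]

_REFERENCE_DIAGONAL = math.hypot(512, 512)  # tolerances quoted at 512x512


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place; defaults follow the method.

    ``simplify_tolerance`` and ``offset_threshold`` are quoted at a 512x512
    canvas and scaled with the input image diagonal when ``scale_tolerances``
    is set.
    """

    threshold: float = 128
    invert: bool = False
    epsilon: float = 0.2
    tau_factor: float = 2.0
    simplify_tolerance: float = 5.0
    offset_threshold: float = 5.0
    scale_tolerances: bool = True
    min_speck: int = 5
    spur_threshold: float = 15.0  # px; drop shorter branch polylines (thinning spurs)
    include_all: bool = False  # map all nodes when the pruned core is empty
    layout: LayoutParams = field(default_factory=LayoutParams)
    seed: int = 0

    def scaled(self, value: float, shape) -> float:
        if not self.scale_tolerances:
            return value
        return value * math.hypot(shape[1], shape[0]) / _REFERENCE_DIAGONAL


@dataclass
class PipelineRun:
    """Everything a run produced, for logging, export and assertions."""

    chain: Chain
    labels: list
    mapping: NodeLineMapping
    constraints: ConstraintSet
    anchors: dict
    constrained: LayoutResult
    result: LayoutResult

    @property
    def mapping_kind(self) -> str:
        return self.mapping.kind

    def summary(self) -> dict:
        sat = [e["satisfied"] for e in self.constrained.constraint_report]
        return {
            "segments": len(self.chain.segments),
            "closed": self.chain.closed,
            "labels": list(self.labels),
            "mapping_kind": self.mapping_kind,
            "mapped_nodes": sum(self.mapping.counts),
            "relative_constraints": len(self.constraints.relatives),
            "alignment_constraints": len(self.constraints.alignments),
            "constraints_satisfied": int(sum(sat)),
            "constraints_total": len(sat),
            "fidelity": self.result.fidelity,
        }


def extract_chain(image: np.ndarray, config: PipelineConfig | None = None) -> Chain:
    """Step 1: sketch raster -> simplified, ordered segment chain."""
    config = config or PipelineConfig()
    mask = img_mod.binarize(image, config.threshold, invert=config.invert)
    mask = img_mod.remove_specks(mask, config.min_speck)
    skel = img_mod.thin(mask)
    polylines = img_mod.extract_polylines(skel)
    if not polylines:
        raise ValueError("sketch skeleton yielded no polylines")
    # spur pruning: jittered strokes leave short branch polylines at
    # junctions after thinning; drop them as long as something remains
    spur = config.scaled(config.spur_threshold, image.shape)
    kept = [p for p in polylines
            if np.linalg.norm(np.diff(p, axis=0), axis=1).sum() >= spur]
    if kept and len(kept) < len(polylines):
        logger.info("pruned %d spur polyline(s) shorter than %.1f px",
                    len(polylines) - len(kept), spur)
        polylines = kept
    tol = config.scaled(config.simplify_tolerance, image.shape)
    off = config.scaled(config.offset_threshold, image.shape)
    simplified = [simplify_polyline(p, tol) for p in polylines]
    return build_chain(simplified, off)


def run_pipeline(graph: nx.Graph, image: np.ndarray,
                 config: PipelineConfig | None = None) -> PipelineRun:
    """Execute extraction -> mapping -> constraints -> layout -> refinement."""
    config = config or PipelineConfig()
    chain = extract_chain(image, config)
    logger.info("chain: %d segments, closed=%s", len(chain.segments), chain.closed)

    pruned = prune(graph, include_all=config.include_all)
    seq = choose_sequence(pruned, chain.closed, tau_factor=config.tau_factor,
                          seed=config.seed)
    mapping = distribute(chain, seq)
    anchors = target_positions(chain, mapping)

    labels = [classify(s, config.epsilon) for s in chain.segments]
    constraints = generate(mapping, labels)

    params = config.layout
    if params.seed != config.seed:
        params = LayoutParams(**{**asdict(params), "seed": config.seed})
    constrained = run_layout(graph, constraints, anchors, params)
    result = refine(graph, constrained, params, constraints=constraints)
    run = PipelineRun(chain=chain, labels=labels, mapping=mapping,
                      constraints=constraints, anchors=anchors,
                      constrained=constrained, result=result)
    logger.info("pipeline summary: %s", run.summary())
    return run


def run_pipeline_files(graph_path, sketch_path, config: PipelineConfig | None = None,
                       out_path=None, svg_path=None, constraints_path=None,
                       graphml_path=None) -> PipelineRun:
    """File-based wrapper: read the graph and sketch, run, write outputs."""
    graph = read_graph(graph_path)
    image = img_mod.load_image(sketch_path)
    run = run_pipeline(graph, image, config)
    if out_path:
        write_positions_json(run.result.positions, out_path)
    if svg_path:
        write_svg(nx.Graph(graph), run.result.positions, svg_path)
    if constraints_path:
        with open(constraints_path, "w") as fh:
            fh.write(run.constraints.to_fcose_json())
    if graphml_path:
        write_graphml_with_positions(graph, run.result.positions, graphml_path)
    return run
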