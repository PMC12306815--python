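# Methods

This note documents the models, parameters and numerical choices behind
`sketchlayout`, and what the synthetic fixtures do and do not demonstrate.

## Pipeline model and assumptions

The method assumes the sketch is a single connected stroke — consecutive
line segments, optionally closing into a loop — drawn dark-on-light at a
typical resolution around 512×512. Branching and disconnected sketches are
out of scope: the chain builder raises `BranchingSketchError` when polylines
cannot be ordered into one open or closed chain. The graph is treated as
undirected for mapping; it is assumed to have a reasonably uniform degree
distribution, since nodes are apportioned to segments purely by segment
length.

## Stage 1 — segment extraction

* **Binarization**: foreground = intensity < `threshold` (default 128;
  `invert` flips the polarity). An Otsu-style automatic threshold was
  considered unnecessary because strokes are near-black by construction,
  but the threshold is fully configurable.
* **Speck removal**: 8-connected components below `min_speck` (= 5 px) are
  dropped before thinning. Freehand input is noisy; without this a single
  stray dot aborts chaining.
* **Thinning**: the classical two-subiteration Zhang–Suen scheme iterated
  to its fixed point, implemented directly from the deletion rules
  (2 ≤ B(p) ≤ 6 neighbours, exactly one 0→1 transition around the ring,
  and the two neighbour-product conditions per subiteration). The fixed
  point makes idempotence structural rather than empirical. Note that
  library implementations of "Zhang" thinning differ by a few pixels at
  branch tips and block centres; the test suite checks topological
  equivalence against scikit-image's variant, not pixel equality.
* **Polyline tracing**: the skeleton's 8-adjacency graph (redundant
  diagonal links removed) is decomposed by edge-consuming walks seeded at
  endpoints, then junction leftovers, then cycles. At a junction the walk
  keeps the branch that best preserves its heading; the rest seed later
  walks. This realizes the extraction contract — full coverage, endpoints
  preserved — with a simple traced-path algorithm instead of a recursive
  region-splitting scheme, matching the package's stated scope (no
  branching support beyond best effort).
* **Spur pruning**: jitter leaves short branch polylines (a few pixels) on
  the skeleton. Polylines shorter than `spur_threshold` (15 px at 512×512,
  scaled with the image diagonal) are dropped as long as something remains.
* **Simplification**: Ramer–Douglas–Peucker. By default RDP runs over the
  full point sequence (`high_quality=True`), so sharp corners are retained
  exactly and the deviation bound — every original point within `tolerance`
  of the simplified polyline — holds by construction. The
  `high_quality=False` path applies the radial-distance prefilter first
  (faster on pixel-dense polylines); because the prefilter can hide a point
  from RDP's deviation test, an exhaustive verify-and-reinsert step restores
  the bound unconditionally. Default tolerance: 5 px at 512×512, scaled
  with the diagonal.
* **Chaining**: greedy assembly — repeatedly attach the polyline whose
  (possibly reversed) endpoint lies nearest to a free chain end, requiring
  the gap to be below `offset_threshold` (5 px); paired endpoints snap to
  their midpoint, so the shared-endpoint invariant holds bit-exactly. The
  chain closes when its two outer ends also meet within the threshold.

## Stage 2 — mapping

* **Pruning** is a single pass over original degrees (`deg > 1`), not
  iterative 2-core peeling — repeated peeling would dissolve path-like
  graphs entirely. Iterative behaviour can be emulated by calling `prune`
  repeatedly if ever wanted; the pipeline does not.
* **Cycle threshold**: a cycle is accepted when its length reaches
  τ = ⌈`tau_factor`·√|V′|⌉ with `tau_factor` = 2.0. The square-root form is
  the only reading under which the acceptance test is satisfiable at all
  (a simple cycle can never reach 2·|V′|), and it admits C_n for all
  n ≥ 9.
* **Cycle search** is a DFS from each not-yet-visited node (seeded-shuffled
  order, so results are deterministic per seed), recording the longest
  back-edge cycle on the current stack. Work is capped at 50·(|V|+|E|)
  traversal steps to keep the stage linear; the cap is configurable.
  Exact longest-cycle search is NP-hard and deliberately out of scope — the
  tests only require that returned cycles are valid and never longer than
  the brute-force optimum.
* **Double sweep**: BFS from a seeded-random node of the largest component
  finds the farthest node (ties to smallest id); a second BFS from there
  yields the visit order and tree parents. The parent map for the path case
  is the BFS-tree parent (so every relative constraint is anchored to a
  graph edge); for the cycle case it is the cycle predecessor, with the
  first node's parent being the last.
* **Apportionment** uses the largest-remainder method with remainder ties
  to the lower segment index: deterministic and exactly conserving.
* **Anchors** place the kᵢ nodes of segment i at interior fractions
  j/(kᵢ+1) — evenly spaced, never on segment junctions.

## Stage 3 — constraints

Direction labels follow image coordinates (y down). The horizontal test
runs before the vertical one; for ε < 1 they are mutually exclusive. A
relative constraint pairs each mapped node with its traversal predecessor
and takes the label of the *node's own* segment (this covers segment
boundaries naturally). Alignment groups are per-segment and never merged
across segments. Contradictions — a new ordering whose reverse is already
implied directly or transitively — are dropped first-come-wins with a
warning; the surviving relative constraints therefore always form a DAG
per axis, which the layout stage depends on.

## Stage 4 — layout

* Force model: Fruchterman–Reingold-style with attraction d²/k along edges
  and repulsion k²/d pairwise, k = `ideal_edge_length` (50 px). Per-node
  steps are capped by a temperature cooling linearly from k/2 to 1 px over
  `iterations` (500).
* Repulsion is computed exactly up to 1500 nodes and via a KD-tree
  neighbour list with cutoff 3k above that, keeping per-iteration cost
  near-linear at the few-thousand-node scale.
* Projection: each iteration runs up to 10 alternating sweeps — alignment
  groups to their mean coordinate, then violated relative constraints
  repaired symmetrically to separation `gap` (10 px). Both are projections
  onto convex sets, so the sweeps are stable; they need not fully converge
  mid-optimization.
* Final projection: pairwise sweeps propagate orderings only one link per
  sweep, which stalls on chains of hundreds of constraints. The final phase
  therefore alternates alignment averaging with an *exact* repair of the
  relative DAG: one topological pass raises each coordinate to
  max(predecessors)+gap and recentres the column. This drives every
  residual below 1e-6 in a handful of sweeps regardless of scale; the loop
  caps at 2000 sweeps and logs a warning if ever short (not observed on
  any fixture).
* Initialization: constrained nodes at their anchors; degree-one nodes at a
  random offset (0.25–0.75·k) from their unique neighbour, placed in passes
  so chains of satellites resolve; any remainder uniformly in the anchor
  bounding box. All randomness flows from one seed; layouts are
  bit-reproducible.
* Refinement: `refine_iterations` (30) unconstrained iterations at low
  temperature (k/10 → 0.5 px) with each node's *total* displacement clamped
  to `refine_cap` (k/2). Refinement may violate constraints slightly; the
  satisfaction report can be recomputed on refined positions, and the
  pipeline stores both the constrained and the refined results.
* Fidelity: standardized Procrustes disparity between final positions and
  anchors over their shared nodes, reported as 1 − disparity clamped to
  [0, 1]. It is invariant under translation, rotation, scaling (and
  reflection); degenerate zero-variance configurations score 0.

## Synthetic fixtures

The generators produce what the pipeline is designed to consume: rasterized
strokes (line, L, rectangle, circle as a 72-gon, zigzag) with Gaussian
per-vertex jitter emulating freehand wobble, and graphs (C_n, P_n, random
labelled trees, tree-plus-random-edges sparse graphs) that are connected by
construction. They deliberately do not model several properties of real
input: pressure-varying or anti-aliased stroke rendering, pen lift-offs and
retraced lines, scanned-paper noise, or graphs with highly skewed degree
distributions. Passing tests therefore demonstrate the pipeline's contracts
(topology preservation, deviation bounds, conservation, constraint
satisfaction, shape fidelity) under clean-to-mildly-noisy conditions, not
robustness to arbitrary hand-drawn input — the chain builder is expected to
reject heavily broken strokes rather than guess.

Problem sizes used by the test suite and the acceptance script — 20 thinning
shapes, 100 simplification polylines, 1000 apportionment trials, cycles up
to C₆₀, brute-force cycle checks on graphs of ≤ 10 nodes, end-to-end runs at
20–40 nodes and one scale run at 2000 nodes / 2512 edges — were chosen to
exercise each contract thoroughly while keeping a full run fast on a single
CPU; the scale run mirrors the largest configuration the method targets.

## Known limitations

* Branching/disconnected sketches: rejected (best-effort tracing exists,
  but the chain stage requires one stroke).
* Closed-loop mapping needs both a closed chain and an acceptable cycle;
  every other combination falls back to the path strategy.
* Long relative-constraint chains impose a minimum drawing extent
  (≈ gap · nodes-per-direction); on dense mappings this enlarges the layout
  relative to the sketch, which the similarity-invariant fidelity absorbs
  but absolute-coordinate consumers should expect.
* Disconnected graph cores: only the largest component is mapped; the rest
  is laid out unconstrained (with a warning).
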