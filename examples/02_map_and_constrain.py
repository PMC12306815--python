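"""Map a graph onto a sketch chain and emit placement constraints.

Builds a 20-cycle and a circle sketch, distributes the graph's cycle over
the chain proportionally to segment lengths, and prints the generated
relative-placement / alignment constraints in the fCoSE option schema.
"""

import networkx as nx

from sketchlayout import (PipelineConfig, SketchSpec, choose_sequence, classify,
                          distribute, extract_chain, generate, prune, render_sketch)

image, _ = render_sketch(SketchSpec("circle", jitter=1.0, seed=2))
chain = extract_chain(image, PipelineConfig())
graph = nx.cycle_graph(20)

core = prune(graph)
seq = choose_sequence(core, chain.closed, seed=0)
mapping = distribute(chain, seq)
labels = [classify(s) for s in chain.segments]
constraints = generate(mapping, labels)

print(f"mapping kind: {seq.kind}; nodes per segment: {mapping.counts}")
print(f"{len(constraints.relatives)} relative constraints, "
      f"{len(constraints.alignments)} alignment groups")
print(constraints.to_fcose_json()[:400], "...")

# The cycle of 20 nodes is apportioned across the chain's segments
# (counts above sum to 20); each node/predecessor pair yields constraints
# oriented by its segment's direction label, exported in a JSON schema a
# constrained layout engine consumes directly.
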