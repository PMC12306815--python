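"""Extract ordered line segments from a sketch raster.

Renders a jittered rectangle stroke, skeletonizes it, and reduces the
skeleton to a chain of simplified segments with direction labels.
"""

from sketchlayout import PipelineConfig, SketchSpec, classify, extract_chain, render_sketch

image, _truth = render_sketch(SketchSpec("rectangle", stroke_width=3, jitter=1.0, seed=4))
chain = extract_chain(image, PipelineConfig())

print(f"chain: {len(chain.segments)} segments, closed={chain.closed}, "
      f"total length {chain.total_length:.0f} px")
for seg in chain.segments:
    print(f"  {seg.start[0]:6.1f},{seg.start[1]:6.1f} -> "
          f"{seg.end[0]:6.1f},{seg.end[1]:6.1f}  [{classify(seg)}]")

# A clean rectangle reduces to exactly 4 segments labelled around the loop
# (t-b / l-r / b-t / r-l in some rotation); "closed=True" means the chain's
# last endpoint snapped back onto its first, so cycle mapping is eligible.
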