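"""Exceptions raised by the sketch-to-layout pipeline."""


class SketchLayoutError(Exception):
    """Base class for pipeline errors."""


class BlankSketchError(SketchLayoutError):
    """Raised when binarization finds no foreground pixels ("blank sketch")."""


class BranchingSketchError(SketchLayoutError):
    """Raised when polylines cannot be assembled into one open or closed
    chain ("branching or disconnected sketch")."""


class NoCoreError(SketchLayoutError):
    """Raised when pruning leaves no node of degree > 1
    ("graph has no multi-degree core")."""


class GraphFormatError(SketchLayoutError):
    """Raised on malformed graph input files; carries the offending line."""
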