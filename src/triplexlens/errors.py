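"""Exception types shared across triplexlens modules."""


class TriplexLensError(Exception):
    """Base class for all triplexlens errors."""


class ValidationError(TriplexLensError):
    """Invalid user input (alphabet, parameter range, malformed record)."""


class BoundsError(TriplexLensError):
    """Sequence or frame coordinates outside the addressable range."""


class AmbiguityError(TriplexLensError):
    """An operation that must not guess found zero or multiple candidates."""


class SchemaError(TriplexLensError):
    """File contents inconsistent with the declared topology/schema."""


class TopologyError(TriplexLensError):
    """Structurally invalid topology (roles, levels, parentage)."""


class DegeneracyError(TriplexLensError):
    """Numerically degenerate geometry (collinear/coincident selection)."""


class ExclusionError(TriplexLensError):
    """A per-level quantity was requested for an excluded (terminal) level."""


class SingularityError(TriplexLensError):
    """Evaluation at a singular point (e.g. zero interatomic distance)."""


class DataError(TriplexLensError):
    """Required rows/columns missing from a quantification table."""
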