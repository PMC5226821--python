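"""Exception hierarchy shared across the package."""


class M6ADriverError(Exception):
    """Base class for all package errors."""


class FormatError(M6ADriverError):
    """A file does not match the expected dialect (missing column, bad row)."""


class ValidationError(M6ADriverError):
    """A parsed value violates its domain (e.g. FDR outside [0, 1])."""


class EmptyNetworkError(M6ADriverError):
    """Parsing or preprocessing left no usable edges."""


class MissingNodeError(M6ADriverError, KeyError):
    """A queried gene is not a node of the network."""


class RandomizationError(M6ADriverError):
    """The network cannot be rewired (fewer than two edges)."""


class ProvenanceError(M6ADriverError):
    """A null model was built on a different network than the one supplied."""
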