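"""Exception hierarchy shared across the pipeline stages."""


class FlocktraceError(Exception):
    """Base class for all package errors."""


class FormatError(FlocktraceError):
    """Input file violates the expected tabular schema."""


class EmptyStreamError(FlocktraceError):
    """A logger file contains no data rows."""


class ValidationError(FlocktraceError):
    """A record violates a domain invariant (e.g. latitude out of range)."""


class ParameterError(FlocktraceError):
    """A numeric parameter is outside its admissible range."""


class ClassificationError(FlocktraceError):
    """A land-cover class name has no category mapping."""


class EmptyMapError(FlocktraceError):
    """A habitat map was loaded but carries no usable polygon."""


class OrderingError(FlocktraceError):
    """Timestamps are not strictly increasing where the operation requires it."""


class RangeError(FlocktraceError):
    """Coordinates fall outside the supported local extent."""


class IntegrityError(FlocktraceError):
    """Conflicting duplicate keys found while merging streams."""


class DegenerateInputError(FlocktraceError):
    """Input is structurally valid but statistically degenerate."""


class SelectionError(FlocktraceError):
    """No eligible candidate model survives the selection filters."""


class ConfigError(FlocktraceError):
    """Pipeline configuration fails validation."""
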