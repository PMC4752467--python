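"""Exception hierarchy.

Validation problems (bad input data, schema mismatches) and computation
problems (degenerate numerics) are kept separate so the CLI can map them
to distinct exit codes.
"""


class FingerqcError(Exception):
    """Base class for all package errors."""


class ValidationError(FingerqcError):
    """Input data violates a documented contract."""


class SchemaError(ValidationError):
    """A required column or field is missing or malformed."""


class ParseError(ValidationError):
    """A cell could not be converted to the expected type."""


class AmbiguousPeakError(ValidationError):
    """One batch contributed more than one peak to a retention-time cluster."""


class EmptyResultError(ValidationError):
    """An operation produced no usable output (e.g. zero common peaks)."""


class ComputationError(FingerqcError):
    """A numerical operation is undefined for the given inputs."""


class DegenerateInputError(ComputationError):
    """Zero-norm vector, constant response, all-missing column, etc."""


class DimensionError(ComputationError):
    """Vector/matrix shapes are incompatible."""
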