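"""Exception hierarchy shared across the pipeline stages."""


class EcgPipeError(Exception):
    """Base class for all package errors."""


class FormatError(EcgPipeError, ValueError):
    """A file or stream does not conform to its declared format."""


class InvalidArgumentError(EcgPipeError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(EcgPipeError, ValueError):
    """Not enough samples/peaks/pairs to perform the operation."""


class UndefinedMetricError(EcgPipeError, ArithmeticError):
    """A metric is mathematically undefined for the given table."""
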