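"""Exception hierarchy shared across the pipeline.

Validation and parse failures map to CLI exit code 2, numerical
failures to exit code 3.
"""


class StromasigError(Exception):
    """Base class for all package errors."""


class ParseError(StromasigError, ValueError):
    """Malformed input file (bad header, non-numeric cell, bad dialect)."""


class DomainError(StromasigError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ValidationError(StromasigError, ValueError):
    """A container invariant or precondition is violated."""


class NumericalError(StromasigError, RuntimeError):
    """A numerical routine failed to produce a usable result."""
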