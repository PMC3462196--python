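"""Exception hierarchy.

``PBCNError`` is the base for every error this package raises on invalid
user input; the CLI maps it to exit code 2.  Anything else escaping the
library is a bug and maps to exit code 1.
"""


class PBCNError(Exception):
    """Base class for all validation and input errors."""


class NetworkSyntaxError(PBCNError):
    """Malformed network document or Boolean expression.

    Carries the 1-based ``line`` and ``column`` of the offending token when
    the error arises inside an expression.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class NetworkValidationError(PBCNError):
    """Structurally well-formed document that violates a model invariant."""


class StateSpaceCapError(NetworkValidationError):
    """More internal nodes than the configured cap allows."""


class BoundaryProbabilityError(PBCNError):
    """A stochastic-input probability on or outside the open interval (0, 1).

    Boundary values change the generating semigroup of the chain and with it
    the recurrent class structure, so they are rejected rather than clamped.
    """


class ScheduleError(PBCNError):
    """Invalid control schedule (gaps, overlaps, out-of-range control values)."""
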