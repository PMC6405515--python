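"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (validation -> 2, infeasibility -> 3,
I/O -> 4), so library code should raise the most specific class that applies.
"""


class LiverfluxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LiverfluxError):
    """Input violates a declared invariant (bad ids, bounds, fractions...)."""


class FormatError(ValidationError):
    """A file does not parse in its declared dialect."""


class InfeasibleError(LiverfluxError):
    """An LP has no feasible flux vector under the applied bounds."""

    def __init__(self, message: str, solver_status: str | None = None):
        super().__init__(message)
        self.solver_status = solver_status


class DegenerateScoreError(LiverfluxError):
    """Raised when the z-transform is undefined (all raw scores identical)."""
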