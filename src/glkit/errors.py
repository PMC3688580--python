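"""Exception hierarchy shared by all glkit modules.

``InputError`` maps to CLI exit code 2, ``AnalysisError`` (and subclasses)
to exit code 3.
"""


class GlkitError(Exception):
    """Base class for all package errors."""


class InputError(GlkitError):
    """Invalid user input: bad concentrations, malformed files, missing chains."""


class SchemeError(InputError):
    """Structurally invalid kinetic scheme (disconnected graph, bad edge)."""


class PartitionError(InputError):
    """Domain partition does not resolve to atoms of the model."""


class AnalysisError(GlkitError):
    """A computation could not be completed on valid input."""


class ConvergenceError(AnalysisError):
    """An iterative fit failed to converge."""


class IdentifiabilityError(AnalysisError):
    """The experimental design cannot constrain a named parameter."""

    def __init__(self, parameter: str, message: str | None = None):
        self.parameter = parameter
        super().__init__(message or f"parameter {parameter!r} is not identifiable from this design")


class PatternUndefinedError(AnalysisError):
    """Reciprocal plots are too non-linear for a Cleland pattern call."""
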