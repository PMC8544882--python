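"""Exception hierarchy shared across the package."""


class CoralithError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CoralithError, ValueError):
    """A physical or mathematical precondition is violated (bad input value)."""


class SchemaError(CoralithError, ValueError):
    """A tabular input does not match the expected column schema."""


class FitError(CoralithError, RuntimeError):
    """A statistical model could not be fitted."""


class DegenerateFitError(FitError):
    """The fit is degenerate (e.g. zero residual variance everywhere)."""
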