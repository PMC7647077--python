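"""Exception hierarchy for netten."""


class NettenError(Exception):
    """Base class for all netten-specific errors."""


class InvalidArgumentError(NettenError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(NettenError, RuntimeError):
    """An operation was invoked on an object in the wrong state (e.g. unfitted)."""


class DegenerateFitError(NettenError, RuntimeError):
    """A regression fit cannot be carried out (e.g. all-zero kernel weights)."""


class DegenerateInputError(NettenError, ValueError):
    """An input matrix is rank-deficient or otherwise degenerate."""


class OptimizationFailureError(NettenError, RuntimeError):
    """The optimizer diverged; carries diagnostic information."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []


class DegenerateTableError(NettenError, ValueError):
    """A contingency table has an empty margin."""


class ParseError(NettenError, ValueError):
    """A data file failed validation on load."""
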