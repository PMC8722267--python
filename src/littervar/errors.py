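"""Typed exceptions shared across the package."""


class LittervarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LittervarError, ValueError):
    """A configuration value is invalid (negative variance, empty design, ...)."""


class InputError(LittervarError, ValueError):
    """An input table is malformed (missing column, non-numeric values, ...)."""


class PedigreeError(LittervarError, ValueError):
    """The pedigree is inconsistent (cycles, unknown parents referenced, ...)."""


class SingularDesignError(LittervarError, ValueError):
    """The fixed-effect design matrix is rank deficient."""

    def __init__(self, message, aliased=None):
        super().__init__(message)
        self.aliased = list(aliased) if aliased is not None else []


class ConvergenceError(LittervarError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class InvariantError(LittervarError, ValueError):
    """A documented data invariant is violated."""
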