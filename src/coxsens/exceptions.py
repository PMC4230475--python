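"""Exception hierarchy shared across the package."""


class CoxsensError(Exception):
    """Base class for package errors."""


class ValidationError(CoxsensError):
    """Input data or parameters violate a precondition."""


class ConfigurationError(CoxsensError):
    """A configuration (column map, scenario file, grid) is malformed."""


class NumericalError(CoxsensError):
    """A solver or quadrature failed to reach its tolerance."""


class ConvergenceError(NumericalError):
    """Iterative fitting failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
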