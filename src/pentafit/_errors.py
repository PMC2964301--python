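"""Exception hierarchy shared across the package."""


class PentafitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PentafitError, ValueError):
    """A table or config file does not have the expected structure."""


class ValidationError(PentafitError, ValueError):
    """Values are structurally readable but violate a domain invariant."""


class InsufficientDataError(PentafitError, ValueError):
    """Too few points/openings/concentrations for the requested analysis."""


class DomainError(PentafitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FitFailureError(PentafitError, RuntimeError):
    """A nonlinear fit did not converge (and no fallback applies)."""
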