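"""Exception hierarchy shared across the package."""


class PherokinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PherokinError, ValueError):
    """An input violates a documented precondition (names the offending field)."""


class InsufficientDataError(PherokinError, ValueError):
    """Too few usable observations for the requested fit."""


class StateConsistencyError(PherokinError, ValueError):
    """A reactor state is internally inconsistent (e.g. ES exceeds total enzyme)."""


class IntegrationFailureError(PherokinError, RuntimeError):
    """Numerical integration produced NaN or a concentration below tolerance."""

    def __init__(self, message: str, step: int | None = None, tau: float | None = None):
        super().__init__(message)
        self.step = step
        self.tau = tau


class NormalizationError(PherokinError, ValueError):
    """A normalization reference (t=0 activity, standard response) is missing or zero."""


class ExtrapolationError(PherokinError, ValueError):
    """Inverse prediction outside the calibrated range with extrapolation disabled."""
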