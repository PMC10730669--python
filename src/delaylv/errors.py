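"""Exception types shared across the package."""


class DelayLVError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DelayLVError, ValueError):
    """A parameter violates its domain (e.g. non-positive rate, non-integer shape)."""


class DomainError(DelayLVError, ValueError):
    """A function argument lies outside the mathematical domain of the operation."""


class StructureError(DelayLVError, ValueError):
    """A state vector or container does not match the expected layout."""


class ExistenceError(DelayLVError, RuntimeError):
    """An equilibrium was requested that does not exist for the given parameters."""


class DegenerateRegimeError(DelayLVError, RuntimeError):
    """a1*a2 == b1*b2 within tolerance: the nullclines are parallel and the
    interior equilibrium is not an isolated point."""


class PoleError(DelayLVError, ValueError):
    """A characteristic function was evaluated at one of its excluded poles."""


class IntegrationError(DelayLVError, RuntimeError):
    """The ODE solver failed; carries the last time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class ValidationError(DelayLVError, ValueError):
    """A scenario configuration failed schema validation; names the offending field."""
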