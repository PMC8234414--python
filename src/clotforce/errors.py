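"""Exception and warning types shared across the package."""


class ClotForceError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(ClotForceError, ValueError):
    """A beam dimension is non-positive or otherwise unphysical."""


class InvalidDesignError(ClotForceError, ValueError):
    """A suspension design violates its structural constraints."""


class DomainError(ClotForceError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(ClotForceError, ValueError):
    """Too few data points to perform the requested computation."""


class DegenerateInputError(ClotForceError, ValueError):
    """Input has no variation along the dimension the computation needs."""


class DataQualityError(ClotForceError, ValueError):
    """A measured trace fails a data-quality gate (e.g. large negative deflection)."""


class BelowBackgroundError(ClotForceError, ValueError):
    """ELISA signal does not exceed the blank background."""


class InvalidLaneError(ClotForceError, ValueError):
    """A blot lane has non-positive band intensities."""


class NoPathToOutputError(ClotForceError, ValueError):
    """A perturbation target has no directed path to the network output node."""


class UnknownReagentError(ClotForceError, KeyError):
    """A reagent label is not present in the perturbation bindings."""


class OverStrokeWarning(UserWarning):
    """Deflection exceeds the chip's nominal stroke (hardware can overshoot)."""


class PlatformFitWarning(UserWarning):
    """A solved connection-arm length exceeds the platform half-width."""


class SingleValueWarning(UserWarning):
    """A group summary was requested for a single observation (SD undefined)."""
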