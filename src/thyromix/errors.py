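"""Exception hierarchy for the thyromix pipeline."""


class ThyromixError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ThyromixError, ValueError):
    """A configuration or generating-parameter object violates its invariants."""


class InsufficientDataError(ThyromixError, ValueError):
    """Too few usable observations for the requested operation."""


class DegenerateDataError(ThyromixError, ValueError):
    """Input data carry no spread (all values equal, zero bandwidth, ...)."""


class DegenerateComponentError(ThyromixError, ValueError):
    """A mixture component collapsed to zero spread or zero weight."""


class DomainError(ThyromixError, ValueError):
    """Values outside the mathematical domain of the requested family."""


class FitError(ThyromixError, RuntimeError):
    """Mixture fitting failed or an unconverged fit was used where a converged
    one is required."""


class InvalidWeekError(ThyromixError, ValueError):
    """Gestational week below the first-trimester lower bound or missing."""
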