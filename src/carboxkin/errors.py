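"""Exception hierarchy for carboxkin.

All package-specific failures derive from :class:`CarboxkinError` so callers
can catch one base class; subclasses distinguish validation problems (bad
parameters, malformed tables) from domain problems (inputs outside the region
where a quantity is defined) and from data-driven fitting failures.
"""


class CarboxkinError(Exception):
    """Base class for all carboxkin errors."""


class ValidationError(CarboxkinError, ValueError):
    """A parameter set, configuration or record violates its invariants."""


class DomainError(CarboxkinError, ValueError):
    """An input lies outside the mathematical domain of an operation
    (negative time, non-positive absolute pressure, zero denominator...)."""


class InsufficientDataError(CarboxkinError):
    """Too few data points to fit the requested model (N must exceed the
    number of free parameters)."""


class DegenerateSeriesError(CarboxkinError):
    """The series carries no usable signal (e.g. all concentrations zero),
    so no fit is attempted."""


class UndefinedStatisticError(CarboxkinError):
    """A statistic is undefined for the given data (e.g. R² with zero
    variance in the observations)."""


class NoFitError(CarboxkinError):
    """Every candidate model failed to fit the series."""


class MismatchError(CarboxkinError):
    """Fit results passed to a comparison do not belong to the same series."""


class SchemaError(CarboxkinError):
    """A tabular input file does not conform to the expected schema."""


class LabellingError(CarboxkinError):
    """An analyte label cannot be mapped to a carbon chain length."""
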