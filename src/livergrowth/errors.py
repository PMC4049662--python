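"""Exception types shared across the package."""


class LiverGrowthError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LiverGrowthError, ValueError):
    """A geometric or model parameter is outside its admissible domain."""


class RangeError(LiverGrowthError, ValueError):
    """A lookup or interpolation target lies outside the covered span."""


class ExtrapolationError(RangeError):
    """An interpolation was requested outside the bracketing data."""


class EmptyRangeError(DomainError):
    """The growth variable has no room to grow (initial == final size)."""


class IncompatibilityError(LiverGrowthError, ValueError):
    """Two objects that must share geometry or initial conditions do not."""


class NumericalError(LiverGrowthError, ArithmeticError):
    """A numerical accumulation produced a non-finite value."""


class SchemaError(LiverGrowthError, ValueError):
    """A configuration or data file violates the expected schema."""


class UnderdeterminedError(LiverGrowthError, ValueError):
    """Too few observations to identify a parameter."""
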