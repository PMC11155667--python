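"""Exception hierarchy.

Everything user-facing derives from :class:`PeakfitError` so callers can
catch one base class at the CLI boundary.
"""


class PeakfitError(Exception):
    """Base class for all package errors."""


class ModelDefinitionError(PeakfitError):
    """The declarative model is malformed (unknown lineshape, bad index...)."""


class InputValidationError(PeakfitError):
    """Numeric/structural validation failed (nonpositive width, bad bounds...)."""


class SpectrumError(PeakfitError):
    """Problems reading or filtering spectral data."""


class ExpressionError(PeakfitError):
    """A constraint expression could not be evaluated."""


class ExpressionCycleError(ExpressionError):
    """The expression dependency graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("cyclic constraint expressions: " + " -> ".join(self.cycle))


class ExpressionSecurityError(ExpressionError):
    """The expression uses a construct outside the arithmetic whitelist."""


class UnderdeterminedError(PeakfitError):
    """Fewer data points than free parameters."""


class DegreesOfFreedomError(PeakfitError):
    """N <= k in a goodness-of-fit computation."""


class LockParseError(PeakfitError):
    """A lock file is not well-formed TOML / misses required fields."""
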