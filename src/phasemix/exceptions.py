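"""Package exception and warning types."""


class PhasemixError(Exception):
    """Base class for package errors."""


class InvalidSeriesError(PhasemixError, ValueError):
    """A patient series violates its invariants."""


class ParseError(PhasemixError, ValueError):
    """An input table could not be parsed."""


class NumericalError(PhasemixError, ArithmeticError):
    """A linear-algebra step failed (e.g. non-positive-definite covariance)."""


class ComponentCollapseError(PhasemixError, RuntimeError):
    """A mixture component lost all its weight during fitting."""


class OccupancyError(PhasemixError, RuntimeError):
    """Too few subjects in a class for an inverse-Wishart conditional."""


class InitializationError(PhasemixError, RuntimeError):
    """Grid-search initialization failed."""


class ConfigError(PhasemixError, ValueError):
    """Invalid simulation or fitting configuration."""


class FitWarning(UserWarning):
    """Non-fatal condition during model fitting (e.g. objective decrease)."""
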