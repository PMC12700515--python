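"""Exception hierarchy for the pipeline.

Configuration problems, malformed data, and numerical failures are kept
distinct so callers can react differently (abort vs. skip vs. retry).
"""


class PhenolmmError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenolmmError, ValueError):
    """Invalid configuration or simulation-truth parameters."""


class DataError(PhenolmmError, ValueError):
    """Malformed or inconsistent input data."""


class NumericError(PhenolmmError, ArithmeticError):
    """A numerical operation failed (e.g. non-positive-definite covariance)."""


class ConvergenceError(PhenolmmError, RuntimeError):
    """An optimizer failed in a way that invalidates a downstream comparison."""


class UnsupportedModelError(PhenolmmError, ValueError):
    """The requested quantity is not defined for this model structure."""


class EligibilityError(PhenolmmError, ValueError):
    """A covariate does not meet the confounder-eligibility rule."""
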