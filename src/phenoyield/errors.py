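"""Exception hierarchy.

All errors raised by this package derive from :class:`PhenoYieldError` so
callers can catch everything domain-specific with one clause while still
letting programming errors (TypeError, ...) propagate.
"""


class PhenoYieldError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PhenoYieldError):
    """Input data or parameters violate a documented precondition."""


class SeasonDetectionError(PhenoYieldError):
    """No usable growing season could be found in a daily NDVI series."""


class AmbiguousPeakError(SeasonDetectionError):
    """Several seasonal peaks of comparable height; caller must disambiguate."""


class PhenologyExtractionError(PhenoYieldError):
    """A stage date could not be extracted (threshold never crossed, etc.)."""


class LogisticFitError(PhenoYieldError):
    """Piecewise-logistic branch fit failed to converge or is degenerate."""

    def __init__(self, message: str, branch: str | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.branch = branch
        self.residual = residual


class ModelingError(PhenoYieldError):
    """Regression input is degenerate (zero variance, length mismatch, ...)."""
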