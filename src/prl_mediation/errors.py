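"""Exception hierarchy shared across the pipeline stages."""


class PRLMediationError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PRLMediationError):
    """A generator or run configuration field is invalid.

    The message always names the offending field.
    """


class CohortValidationError(PRLMediationError):
    """A cohort table violates the column contract or a row invariant."""


class CalibrationError(PRLMediationError):
    """Count-model calibration could not reach the requested targets."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class DegenerateTableError(PRLMediationError):
    """A contingency table has a zero margin."""


class InsufficientDataError(PRLMediationError):
    """Too few observations for the requested statistical test."""


class CollinearityError(PRLMediationError):
    """Design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns or [])


class DegenerateFitError(PRLMediationError):
    """A fitted model has zero residual variance where variation is required."""


class ResamplingDegeneracyError(PRLMediationError):
    """Too many bootstrap replicates produced rank-deficient designs."""


class RenderError(PRLMediationError):
    """An analysis report is incomplete or cannot be rendered."""
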