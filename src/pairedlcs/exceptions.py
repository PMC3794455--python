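"""Exception hierarchy for pairedlcs."""


class PairedLcsError(Exception):
    """Base class for all package-specific errors."""


class DataSizeError(PairedLcsError, ValueError):
    """Raised when a sample is too small (n < 3) for the change regression."""


class DegenerateDataError(PairedLcsError, ValueError):
    """Raised for degenerate inputs: zero wave variance, or a change score
    with zero variance (perfectly uniform change)."""


class SingularModelError(PairedLcsError, ValueError):
    """Raised when an implied or sample covariance matrix is singular or
    not positive definite where positive definiteness is required."""


class ConvergenceError(PairedLcsError, RuntimeError):
    """Raised when the ML optimizer fails to converge after restarts.

    Carries the best point found in ``best_result`` (may be ``None``).
    """

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class NestingError(PairedLcsError, ValueError):
    """Raised when a chi-square difference test is requested for models
    that are not properly nested (constrained df must exceed free df)."""


class ConfigError(PairedLcsError, ValueError):
    """Raised for malformed configuration files or option values."""
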