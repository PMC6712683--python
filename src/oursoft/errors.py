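"""Exception hierarchy shared by all oursoft modules."""


class OursoftError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OursoftError, ValueError):
    """An input is outside the physical or model domain (e.g. temperature
    outside the liquid-water range, negative predicted kLa)."""


class DataError(OursoftError, ValueError):
    """A data series is structurally unusable (non-monotone time, constant
    dissolved-oxygen trace, log of a non-positive deficit, ...)."""


class InsufficientDataError(DataError):
    """Fewer samples than the estimator needs."""


class FitError(OursoftError, RuntimeError):
    """A regression problem is degenerate (rank-deficient design,
    parallel segments, constant regressor)."""


class ConvergenceError(FitError):
    """An iterative fit did not converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SchemaError(OursoftError, ValueError):
    """A delimited-text file does not match the expected column schema."""


class UnavailableChannelError(OursoftError, ValueError):
    """An optional on-line channel (off-gas, capacitance) required by the
    requested computation is missing from the record."""
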