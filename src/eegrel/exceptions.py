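"""Exception hierarchy shared across the package."""


class EegrelError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EegrelError):
    """A segment file contains a line that cannot be parsed as a number."""


class EmptyInputError(EegrelError):
    """A segment file or sample array contains no data."""


class AliasingError(EegrelError):
    """Requested band content lies at or above the Nyquist frequency."""


class InvalidBandError(EegrelError):
    """A frequency band is empty, inverted, or exceeds Nyquist."""


class DegenerateSignalError(EegrelError):
    """An operation is undefined on this signal (e.g. normalizing all zeros)."""


class WindowTooShortError(EegrelError):
    """The analysis window resolves to too few samples."""


class InsufficientLengthError(EegrelError):
    """The segment is shorter than one analysis window."""


class FilterbankConfigError(EegrelError):
    """The filterbank cannot be constructed on the given frequency grid."""


class FilterResolutionError(FilterbankConfigError):
    """A triangular filter covers fewer than two frequency-grid points."""


class ShapeError(EegrelError):
    """Inputs have inconsistent dimensions."""


class DegenerateCovarianceError(EegrelError):
    """The (centered) observation matrix has zero covariance."""


class InsufficientDataError(EegrelError):
    """Too few objects are available for the requested fit."""


class OptimizationFailureError(EegrelError):
    """The hyperparameter search never saw a finite objective value."""


class ConfigError(EegrelError):
    """An invalid run or dataset configuration."""
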