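"""Exception hierarchy for ramancell.

Every contract violation raises a subclass of :class:`RamanError`, so callers
can distinguish pipeline failures from programming errors.
"""


class RamanError(ValueError):
    """Base class for all ramancell contract violations."""


class FormatError(RamanError):
    """Delimited-text table does not match the expected layout."""


class GridError(RamanError):
    """Wavenumber grid violates the ascending-grid convention."""


class AlignmentError(RamanError):
    """Two spectra/datasets do not share the same wavenumber grid."""


class ExtrapolationError(RamanError):
    """Requested grid extends outside a spectrum's measured span."""


class ParameterError(RamanError):
    """Invalid tuning parameter (window size, threshold, level, ...)."""


class DataError(RamanError):
    """Input data insufficient or inconsistent for the requested operation."""


class LabelError(DataError):
    """Class labels missing, single-class, or otherwise unusable."""


class ConfigError(RamanError):
    """Invalid synthetic-data or pipeline configuration."""
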