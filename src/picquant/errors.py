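"""Exception hierarchy shared across the pipeline."""


class PicquantError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PicquantError, ValueError):
    """A supplied parameter violates an operation's precondition."""


class SizingError(ParameterError):
    """An image is too small to contain the requested compartments."""


class ConfigurationError(PicquantError):
    """Required configuration (e.g. a spectral channel) is missing."""


class ResolutionError(PicquantError):
    """A wavelength grid is too sparse for spectral classification."""


class CalibrationError(PicquantError):
    """No intensity level separates the labelled classes."""


class DataError(PicquantError):
    """Input data are invalid (e.g. non-positive reference signal)."""


class FitError(PicquantError):
    """A model fit failed or did not converge."""


class SchemaError(PicquantError):
    """A table does not follow the expected column schema."""
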