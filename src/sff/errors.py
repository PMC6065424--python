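"""Exception hierarchy shared across the package."""


class SFFError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(SFFError, ValueError):
    """Array shapes are incompatible (e.g. vectors of different length)."""


class ParameterError(SFFError, ValueError):
    """A tunable parameter is outside its valid range."""


class DegenerateInputError(SFFError, ValueError):
    """Input is structurally too small or empty for the operation."""


class ConsistencyError(SFFError, ValueError):
    """Two objects that must agree (shape, window, kernel params) do not."""


class ConfigurationError(SFFError, ValueError):
    """A run configuration is invalid."""


class FormatError(SFFError, ValueError):
    """An input file or stack does not match the expected format."""


class ValidationError(SFFError, ValueError):
    """A user-supplied definition (ROI, config file) failed validation."""


class DegenerateWindowError(SFFError, ValueError):
    """A correlation window has (near-)zero variance; NCC is undefined."""


class TrackingInfeasibleError(SFFError, RuntimeError):
    """No ROI offers enough texture to track motion reliably."""
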