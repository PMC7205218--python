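"""Exception hierarchy shared across the pipeline stages."""


class FodeformError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FodeformError, ValueError):
    """A user-supplied parameter is outside its valid domain."""


class DegenerateGeometryError(FodeformError, ValueError):
    """Marker geometry is too degenerate to define a rigid frame."""


class GimbalLockError(FodeformError, ValueError):
    """Cardan decomposition hit the singular configuration."""


class CalibrationError(FodeformError, ValueError):
    """Load-cell calibration could not be performed."""


class DataFormatError(FodeformError, ValueError):
    """An input file does not conform to the expected layout."""


class DivergenceError(FodeformError, RuntimeError):
    """Network training produced a non-finite loss."""


class PipelineError(FodeformError, RuntimeError):
    """A pipeline stage could not run with the given configuration."""
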