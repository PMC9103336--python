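"""Exception types shared across the package."""


class FecgSqiError(Exception):
    """Base class for package-specific errors."""


class ConfigError(FecgSqiError, ValueError):
    """Invalid configuration or argument values."""


class DegenerateSignalError(FecgSqiError, ValueError):
    """A signal is degenerate for the requested operation (e.g. constant
    input to min–max normalization, a dead electrode)."""


class ExtractionError(FecgSqiError, RuntimeError):
    """Maternal-ECG cancellation could not run (e.g. too few beats)."""


class FormatError(FecgSqiError, ValueError):
    """A file does not conform to the expected on-disk format."""
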