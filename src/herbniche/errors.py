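"""Package-wide exception types."""


class HerbnicheError(Exception):
    """Base class for all package errors."""


class GridFormatError(HerbnicheError):
    """A raster file violates the expected on-disk layout."""


class OutOfBoundsError(HerbnicheError):
    """A coordinate falls outside a grid's extent."""


class EmptyDomainError(HerbnicheError):
    """An operation requires at least one valid cell/point and got none."""


class AlignmentError(HerbnicheError):
    """Chromatogram peak alignment failed for a sample."""


class ConfigurationError(HerbnicheError):
    """Invalid or incomplete configuration for an operation."""
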