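"""Exception types shared across the package."""


class BrainGACError(Exception):
    """Base class for all braingac errors."""


class VolumeFormatError(BrainGACError):
    """Raised when a file cannot be read as a supported 3-D image."""


class GeometryError(BrainGACError):
    """Raised when a requested geometric construction does not fit the grid."""


class EmptySliceError(BrainGACError):
    """Raised when an operation requires at least one in-voxel in a slice."""


class NumericalInstabilityError(BrainGACError):
    """Raised when the level-set update produces non-finite values."""


class UndefinedMetricError(BrainGACError):
    """Raised when an overlap index is undefined for the given counts."""


class ExtractionError(BrainGACError):
    """Raised when the full-volume extraction fails on every slice."""
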