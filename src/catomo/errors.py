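"""Exception types shared across the pipeline."""


class CatomoError(Exception):
    """Base class for package errors."""


class FormatError(CatomoError):
    """A file could not be parsed as the expected image format."""


class GeometryError(CatomoError, ValueError):
    """Incompatible or invalid voxel geometry (shape, spacing, origin)."""


class DomainError(CatomoError, ValueError):
    """An argument is outside the operation's mathematical domain."""


class CapacityError(CatomoError, RuntimeError):
    """Object placement in a phantom failed after the bounded attempt budget."""
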