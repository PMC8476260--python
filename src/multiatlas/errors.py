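"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`MultiAtlasError` so callers can catch
one base class; the subclasses distinguish configuration mistakes from bad
inputs from numerical failures.
"""


class MultiAtlasError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MultiAtlasError):
    """A file could not be read as a supported image format."""


class MetadataError(MultiAtlasError):
    """Image header lacks required geometry metadata (spacing/origin/direction)."""


class ValidationError(MultiAtlasError):
    """Input data violates a documented contract (e.g. non-binary label values)."""


class ConfigError(MultiAtlasError):
    """A configuration value is out of range or an option name is unknown."""


class GeometryError(MultiAtlasError):
    """Two images that must share a grid have mismatched geometry."""


class DomainError(MultiAtlasError):
    """A point or index lies outside the supported domain of a transform."""


class DegenerateInputError(MultiAtlasError):
    """Input is degenerate for the requested operation (constant image, empty mask...)."""


class OverlapError(MultiAtlasError):
    """Too few metric samples map inside the moving image domain."""


class OptimizationError(MultiAtlasError):
    """The registration optimizer produced a non-finite metric value."""
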