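"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`TractoprofError`, so
callers (notably the batch pipeline driver, which must not let one failing
tract abort the rest) can catch a single base class.
"""


class TractoprofError(Exception):
    """Base class for all tractoprof errors."""


class FormatError(TractoprofError):
    """A file does not conform to its declared on-disk format."""


class UnsupportedDialectError(FormatError):
    """The file is recognised but uses a dialect we do not read."""


class TruncationError(FormatError):
    """The binary section of a file ends before its declared content."""


class DimensionalityError(TractoprofError):
    """A volume has the wrong number of axes for the requested operation."""


class ValidationError(TractoprofError):
    """An argument violates a documented precondition."""


class EmptyROIError(ValidationError):
    """A region of interest contains no voxels."""


class FrameMismatchError(ValidationError):
    """Two objects do not share the same voxel grid (shape and affine)."""


class InsufficientDataError(ValidationError):
    """Too few usable measurements for a model fit."""


class UndefinedMetricError(TractoprofError):
    """A statistic is undefined for the given inputs (e.g. zero variance)."""
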