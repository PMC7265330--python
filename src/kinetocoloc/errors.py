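"""Exception hierarchy for kinetocoloc.

All package errors derive from :class:`KinetocolocError` so callers can
catch broadly; most also derive from the matching builtin (ValueError,
KeyError, ...) so idiomatic handling keeps working.
"""


class KinetocolocError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(KinetocolocError, ValueError):
    """A parameter violates its documented constraint (e.g. tau <= 0)."""


class DegenerateGeometryError(KinetocolocError, ValueError):
    """Requested synthetic geometry cannot be represented on the voxel grid."""


class DegenerateHistogramError(KinetocolocError, ValueError):
    """Otsu thresholding on a constant image: no separable classes."""


class NoSpotsError(KinetocolocError, ValueError):
    """Spot mask is empty where a nonempty mask is required."""


class EmptyShellError(KinetocolocError, ValueError):
    """Background shell contains no voxels."""


class UndefinedRatioError(KinetocolocError, ZeroDivisionError):
    """Shell mean is non-positive; the scaled colocalization is undefined."""


class ChannelNotFoundError(KinetocolocError, KeyError):
    """Requested channel label is not present in the movie."""


class MissingMetadataError(KinetocolocError, ValueError):
    """Required image metadata (e.g. physical voxel size) absent and not overridden."""


class NormalizationError(KinetocolocError, ValueError):
    """Fluorescence value at the NEBD frame is non-positive."""


class UndefinedRegressionError(KinetocolocError, ValueError):
    """Zero-variance channel: the threshold-sweep regression is undefined."""


class UndefinedPercentError(KinetocolocError, ZeroDivisionError):
    """No reference-channel pixels above threshold: percentage undefined."""


class UndefinedOverlapError(KinetocolocError, ZeroDivisionError):
    """Reference profile integrates to zero: overlap percentage undefined."""


class EmptyAggregateError(KinetocolocError, ValueError):
    """No time point carries a defined value in any trace."""


class ConfigError(KinetocolocError, ValueError):
    """Pipeline configuration document violates the schema."""
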