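"""Exception types shared across the pipeline stages."""


class UsimgenError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(UsimgenError):
    """An inclusion or fiducial could not be placed without overlap."""


class DimensionError(UsimgenError):
    """A volume or image is too small for the requested operation."""


class UnknownLabelError(UsimgenError, KeyError):
    """The requested label name is not present in the volume."""


class EmptyTargetError(UsimgenError):
    """The target mask is empty everywhere."""


class GeometryError(UsimgenError):
    """A geometric precondition is violated (apex outside image, ...)."""


class OversamplingError(UsimgenError):
    """Requested scatterer count exceeds the number of source pixels."""


class RangeError(UsimgenError):
    """A scatterer lies beyond the probe's maximum depth."""


class SamplingError(UsimgenError):
    """The sampling frequency violates the Nyquist criterion."""


class BorderError(UsimgenError):
    """An annotation box would be clipped by the image border."""


class EmptyDatasetError(UsimgenError):
    """A split or export was requested on an empty manifest."""


class UnderdeterminedError(UsimgenError):
    """Too few point correspondences for homography estimation."""


class DegenerateConfigurationError(UsimgenError):
    """Point correspondences are degenerate (e.g., collinear)."""


class ProjectionError(UsimgenError):
    """A point maps to infinity under the projective transform."""
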