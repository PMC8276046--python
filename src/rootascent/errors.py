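"""Exception hierarchy for the toolkit.

Every stage raises a subclass of :class:`RootAscentError` so the CLI can map
failures to stage-tagged exit messages.
"""


class RootAscentError(Exception):
    """Base class for all toolkit errors."""


# --- stitching ---------------------------------------------------------------
class InsufficientKeypointsError(RootAscentError):
    """Too few keypoint matches between the two scan halves."""


class DegenerateGeometryError(RootAscentError):
    """The inlier set does not constrain a homography (e.g. collinear points)."""


class EmptyOverlapError(RootAscentError):
    """The warped halves do not intersect on the merge canvas."""


# --- segmentation ------------------------------------------------------------
class DegenerateHistogramError(RootAscentError):
    """The image is constant; no threshold separates two classes."""


class EmptyForegroundError(RootAscentError):
    """No pixel falls on the root side of the threshold."""


# --- skeleton / path ---------------------------------------------------------
class NotASkeletonError(RootAscentError):
    """Input raster contains a 2x2 all-active block, so it is not 1 px wide."""


class NoAscendingRouteError(RootAscentError):
    """Every branch from every junction was exhausted without reaching the top."""


class PathOffMaskError(RootAscentError):
    """A path pixel lies on background in the mask it is measured against."""


class NoConvergenceError(RootAscentError):
    """Peak suppression left residual peaks after the iteration cap."""


# --- tomography --------------------------------------------------------------
class ZeroOpenBeamError(RootAscentError):
    """The mean open-beam frame contains non-positive pixels."""


class EmptyStackError(RootAscentError):
    """The tomography stack has no voxels."""


# --- synthetic data ----------------------------------------------------------
class RootExitsCanvasError(RootAscentError):
    """Generated root geometry overflows the requested canvas."""


class OverlapTooSmallError(RootAscentError):
    """Requested overlap band is too small to support stitching."""


class UnsortedTimestampsError(RootAscentError):
    """Timestamp labels of a trait series are not mutually orderable."""
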