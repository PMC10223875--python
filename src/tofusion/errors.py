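"""Exception hierarchy for the fusion pipeline.

Every failure mode that callers are expected to handle programmatically has
its own class; all inherit from :class:`ToFusionError` so a pipeline driver
can catch the lot in one clause.
"""


class ToFusionError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ToFusionError, ValueError):
    """A scalar parameter violates its domain (e.g. non-positive wavelength)."""


class InvalidInputError(ToFusionError, ValueError):
    """An array input has the wrong shape, size or dtype for the operation."""


class BehindCameraError(ToFusionError):
    """A 3D point has non-positive depth after transform into the camera frame."""


class GridIncompleteError(ToFusionError):
    """Fewer (or more) keypoints than the calibration grid requires."""


class OrderingFailedError(ToFusionError):
    """Row/column clustering of grid keypoints is ambiguous."""


class NoDepthError(ToFusionError):
    """The organized point cloud holds no finite point at the requested pixel."""


class InsufficientCorrespondencesError(ToFusionError):
    """Fewer than the minimum 6 usable 3D-2D pairs survive."""


class DegenerateConfigurationError(ToFusionError):
    """The pose-estimation system is rank-deficient (degenerate geometry)."""


class CalibrationFailedError(ToFusionError):
    """No frame pair yielded a usable correspondence set."""


class NotCalibratedError(ToFusionError):
    """A fusion operation was invoked without the required extrinsic pose."""


class RoiOutsideCloudError(ToFusionError):
    """A region of interest is not supported by any finite ToF cloud point.

    Cross-modality label projection requires the ROI to lie within the ToF
    point cloud; a box over a cloud hole cannot be transferred.
    """


class VisibilityError(ToFusionError):
    """A synthetic scene object falls outside a camera frustum."""
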