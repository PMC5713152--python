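"""Exception types raised by the pipeline."""


class LitchiVisionError(Exception):
    """Base class for all package-specific errors."""


class PointBehindCameraError(LitchiVisionError):
    """World point has non-positive depth in the camera frame."""


class InvalidPoseError(LitchiVisionError):
    """Rotation matrix is not a proper rotation (orthonormal, det +1)."""


class RankDeficiencyError(LitchiVisionError):
    """Calibration correspondences are degenerate (e.g. coplanar/collinear)."""


class NonPositiveDisparityError(LitchiVisionError):
    """Triangulation requires a strictly positive disparity."""


class ChannelError(LitchiVisionError):
    """Image does not have the expected number of colour channels."""


class PatchSizeError(LitchiVisionError):
    """Patch is too small for the requested texture statistics."""


class BoundsError(LitchiVisionError):
    """Requested window falls outside the image."""


class ParameterError(LitchiVisionError):
    """A tunable parameter is outside its admissible range."""


class DegenerateProblemError(LitchiVisionError):
    """Training or matching problem is degenerate (single class, zero vector...)."""


class UndefinedSimilarityError(LitchiVisionError):
    """Similarity/correlation undefined (zero vector or zero-variance window)."""


class EmptyClusterError(LitchiVisionError):
    """Operation requires at least one member label."""


class LayoutError(LitchiVisionError):
    """Synthetic cluster plan cannot be placed inside the image."""


class MissingModelError(LitchiVisionError):
    """A trained classifier required by the pipeline is missing."""
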