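"""Exception hierarchy shared by all oipf modules."""


class OIPFError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(OIPFError, ValueError):
    """An argument violates a documented precondition."""


class InvalidTransformError(InvalidArgumentError):
    """A matrix is not a rigid transform within the accepted tolerance."""


class DegenerateGeometryError(InvalidArgumentError):
    """Point/landmark configuration is rank-deficient (collinear, coincident)."""


class STLFormatError(OIPFError, IOError):
    """An STL file is malformed or truncated."""


class EmptyMaskError(OIPFError, ValueError):
    """An operation that requires foreground voxels received an empty mask."""


class EmptyCorrespondenceError(OIPFError, RuntimeError):
    """ICP trimming/exclusion left no usable correspondences."""


class StageError(OIPFError, RuntimeError):
    """Pipeline failure wrapped with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


class GimbalLockWarning(UserWarning):
    """Pitch within numerical reach of +/-90 deg; roll fixed to 0 by convention."""


class EmptySegmentationWarning(UserWarning):
    """Thresholding produced no foreground voxels."""


class ShapeMismatchWarning(UserWarning):
    """Registration residual exceeds the same-shape heuristic."""
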