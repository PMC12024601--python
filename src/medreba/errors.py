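"""Exception hierarchy shared across the package."""


class MedrebaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MedrebaError):
    """A landmark frame or table violates the documented schema."""


class EmptyInputError(MedrebaError):
    """An operation received an empty stream, series or file."""


class OrderingError(MedrebaError):
    """Frame indices are not strictly increasing within a stream."""


class AlignmentError(MedrebaError):
    """Synchronization offsets exhaust a stream (no co-indexed frames left)."""


class DegenerateGeometryError(MedrebaError):
    """Input points are collinear/coincident where a well-posed angle or pose
    estimate requires them not to be."""


class EstimationError(MedrebaError):
    """Pose estimation failed to converge or was fed degenerate geometry."""


class ProjectionError(MedrebaError):
    """A 3-D point lies on or behind the camera plane (z <= 0)."""


class BoundsError(MedrebaError):
    """A point, score or table argument lies outside its valid range."""


class SentinelError(MedrebaError):
    """A 0 (occluded) sentinel reached an operation that requires valid grades."""


class FitError(MedrebaError):
    """Regression design matrix is rank-deficient or otherwise unusable."""
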