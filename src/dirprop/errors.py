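"""Exception hierarchy for dirprop."""


class DirpropError(Exception):
    """Base class for all dirprop errors."""


class UnsupportedOrientationError(DirpropError):
    """NIfTI affine is not axis-aligned with positive spacings."""


class EmptyStructureError(DirpropError):
    """An operation requiring a non-empty structure received an empty one."""


class GridMismatchError(DirpropError):
    """Two objects expected on the same voxel grid are on different grids."""


class GeometryError(DirpropError):
    """Requested geometry does not fit the voxel grid."""


class AmbiguousMaskError(DirpropError):
    """Organ masks overlap where disjoint masks are required."""


class UndefinedMetricError(DirpropError):
    """Metric undefined for the given inputs (e.g. two empty masks)."""


class ConvergenceError(DirpropError):
    """An iterative fit failed to converge."""


class SchedulingError(DirpropError):
    """A fraction required by the workflow lacks manual contours."""
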