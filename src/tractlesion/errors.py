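"""Exception hierarchy shared across the pipeline."""


class TractLesionError(Exception):
    """Base class for all package errors."""


class FormatError(TractLesionError):
    """A file on disk is not valid in the expected format."""


class GeometryError(TractLesionError):
    """An affine or coordinate operation is ill-posed (e.g. singular affine)."""


class ValidationError(TractLesionError):
    """Input violates a documented precondition."""


class EmptyMaskError(ValidationError):
    """A binary mask required to be nonempty has no set voxels."""


class OutOfBoundsError(TractLesionError):
    """A world-space point falls outside the volume grid."""


class DesignMatrixError(TractLesionError):
    """A diffusion scheme or regression design cannot support the requested fit."""


class RegressionError(TractLesionError):
    """A regression model cannot be fitted (e.g. rank-deficient design)."""
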