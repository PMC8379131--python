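"""Exception hierarchy shared across pipeline stages."""


class VplctError(Exception):
    """Base class for all pipeline errors."""


class InputError(VplctError):
    """Missing or unreadable input artifact."""


class ShapeError(VplctError):
    """Array has the wrong dimensionality or incompatible shape."""


class DataError(VplctError):
    """Input contains invalid values (non-finite, wrong dtype, ...)."""


class GeometryError(VplctError):
    """Grids (shape/spacing/origin) of two volumes do not match."""


class UsageError(VplctError):
    """API misuse: invalid parameter combination."""


class SegmentationError(VplctError):
    """Lung segmentation found no plausible lung component."""


class DegenerateFieldError(VplctError):
    """Displacement field folds everywhere / Jacobian invalid on all voxels."""


class NormalizationError(VplctError):
    """Vascular reference is empty or non-positive."""


class RoiError(VplctError):
    """A required vessel ROI label is absent."""


class EmptyRegionError(VplctError):
    """Requested region contains no (valid) voxels."""


class SpecError(VplctError):
    """Phantom specification violates its invariants."""


class DegenerateInputError(VplctError):
    """Statistical input with zero variance or too few samples."""


class QCExclusionError(VplctError):
    """Registration quality control triggered the exclusion rule."""
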