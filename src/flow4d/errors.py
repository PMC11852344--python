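"""Exception hierarchy used across the pipeline."""


class Flow4DError(Exception):
    """Base class for all package errors."""


class ValidationError(Flow4DError, ValueError):
    """An object violates its invariants (NaNs, shape mismatch, empty mask, ...)."""


class FormatError(Flow4DError):
    """An on-disk container is missing required datasets or attributes."""


class ConfigError(ValidationError):
    """An analysis-configuration value is out of range; message names the key."""


class DomainError(ValidationError):
    """A closed-form oracle received an argument outside its mathematical domain."""


class InfeasibleTargetError(Flow4DError):
    """No power-law exponent in the allowed range realises the requested targets."""


class ResolutionError(ValidationError):
    """The phantom tube is under-resolved by the requested voxel grid."""


class SegmentationError(Flow4DError):
    """Threshold segmentation produced an empty mask."""


class BorderError(Flow4DError):
    """A mask touches the volume border; pad before extracting a surface."""


class SurfaceCoverageError(Flow4DError):
    """Too many wall-surface sample points fell outside the velocity volume."""


class OutOfBoundsError(Flow4DError):
    """A valve-plane aperture extends outside the velocity volume."""
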