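"""Structured exceptions shared across the pipeline."""


class PhyllosegError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatchError(PhyllosegError):
    """Rasters that must share a shape do not."""


class InvalidParameterError(PhyllosegError):
    """A parameter object violates its documented invariants."""


class GeometryError(PhyllosegError):
    """A frame is too small (or otherwise unsuitable) for the requested
    morphology, e.g. no duct can be placed inside the tissue."""


class EmptyInputError(PhyllosegError):
    """An operation received an empty manifest, split, or sample."""


class TrainingDivergedError(PhyllosegError):
    """The optimizer produced a non-finite loss."""


class SingularCovarianceError(PhyllosegError):
    """Pooled within-class covariance is singular and ridge is disabled."""
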