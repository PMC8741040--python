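"""Exception hierarchy for nucdhl.

Every error raised deliberately by the package derives from :class:`NucdhlError`
so callers can catch the library's failures without masking programming errors.
"""


class NucdhlError(Exception):
    """Base class for all nucdhl errors."""


class ConfigurationError(NucdhlError):
    """A configuration object or lookup key is invalid (unknown group/stain,
    encoder layer audit mismatch, malformed experiment config)."""


class ArgumentError(NucdhlError, ValueError):
    """An argument violates a documented precondition (negative counts,
    degenerate ellipse geometry, probabilities outside [0, 1])."""


class EmptyInputError(NucdhlError):
    """An operation received an empty mask, table or sample list."""


class SegmentationError(NucdhlError):
    """Pre-processing produced an empty segmentation mask; the image is rejected."""


class ScalingError(NucdhlError):
    """Standard scaling failed (e.g. a zero-variance column); the message names
    the offending column."""


class TrainingError(NucdhlError):
    """Model training cannot proceed (e.g. single-class labels)."""


class ShapeError(NucdhlError):
    """An array does not have the shape the operation requires."""


class AuditError(NucdhlError):
    """A reproducibility audit failed (split-hash mismatch across stages)."""
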