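"""Exception hierarchy for the bone-age assessment pipeline.

Errors carry the pipeline stage in their message where relevant so that a
failure in a multi-stage run (``autobaa predict``) is attributable.
"""


class AutoBAAError(Exception):
    """Base class for all package errors."""


class FormatError(AutoBAAError):
    """Unreadable or unsupported image file (e.g. RGB PNG, truncated DICOM)."""


class GeometryError(AutoBAAError):
    """Image too small for the requested operation."""


class ShapeError(AutoBAAError):
    """Array shape incompatible with the model or paired input."""


class UnparseableReportError(AutoBAAError):
    """No bone-age statement could be located in a radiology report."""


class AmbiguousReportError(UnparseableReportError):
    """Multiple conflicting bone-age statements in one report."""


class OutOfCohortError(AutoBAAError):
    """Parsed bone age below 5 years; the study cohort excludes ages 0-4."""


class InsufficientDataError(AutoBAAError):
    """Too few samples to perform the requested split or fit."""


class MissingClassError(AutoBAAError):
    """A pixel class is absent from every ground-truth map in the corpus."""


class TrainingFailureError(AutoBAAError):
    """Loss diverged (NaN) during network training."""


class GridFailureError(AutoBAAError):
    """Every run of a hyperparameter grid search failed."""


class EmptySegmentationError(AutoBAAError):
    """Hand segmentation produced an empty mask."""


class ConfigError(AutoBAAError):
    """Invalid configuration value (unknown layer group, format, etc.)."""


class UndefinedIoUError(AutoBAAError):
    """IoU undefined: both masks of a pair are empty."""
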