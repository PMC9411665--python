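"""Exception hierarchy for the equipain pipeline."""


class EquipainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EquipainError):
    """Invalid study / trial / model configuration."""


class ValidationError(EquipainError):
    """Data failed a schema or range check (names the offending field)."""


class InsufficientDataError(EquipainError):
    """Not enough strides, subjects or rows for the requested computation."""


class SegmentationError(EquipainError):
    """Stride segmentation failed (no dominant periodicity, broken alternation)."""


class DegenerateVarianceError(EquipainError):
    """A variance needed by a statistic is exactly zero."""


class UndefinedROCError(EquipainError):
    """ROC requested with only one class present."""


class ModelFitError(EquipainError):
    """Mixed-model optimizer failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
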