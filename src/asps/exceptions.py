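"""Exception hierarchy for the asps package."""


class ASPSError(Exception):
    """Base class for all package errors."""


class InvalidPriorError(ASPSError):
    """Population prior violates its positivity constraints."""


class InvalidMeasurementError(ASPSError):
    """A ratio measurement is non-positive or non-finite."""


class EmptyInputError(ASPSError):
    """An operation received an empty series or collection."""


class EstimationError(ASPSError):
    """Too little data to estimate population hyperparameters."""


class InsufficientLengthError(ASPSError):
    """A series is too short for the requested statistic."""


class InsufficientObservationsError(ASPSError):
    """An athlete trajectory has fewer occasions than required."""


class SchemaError(ASPSError):
    """A feature / biomarker name is not part of the fixed schema."""


class DegenerateLabelsError(ASPSError):
    """Classifier training data contains a single class."""


class UndefinedAUCError(ASPSError):
    """AUC requested with only one class present."""


class PlanError(ASPSError):
    """Cross-validation plan cannot be built or is inconsistent."""


class ConfigError(ASPSError):
    """Invalid pipeline or simulation configuration."""


class ProfileParseError(ASPSError):
    """Malformed input rows while reading longitudinal profiles."""
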