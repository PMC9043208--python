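"""Exception hierarchy shared across the pipeline."""


class FQRSError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FQRSError):
    """Input file cannot be parsed."""


class SchemaError(FQRSError):
    """Input file parses but violates the expected schema."""


class SamplingRateError(FQRSError):
    """Sampling rate incompatible with a requested operation."""


class DegenerateSignalError(FQRSError):
    """Signal content is degenerate (constant lead, no anchors, ...)."""


class SegmentationFailure(FQRSError):
    """QRS segmentation could not produce a usable result."""


class TrainingError(FQRSError):
    """Classifier training preconditions violated."""


class ScoringError(FQRSError):
    """Model scoring preconditions violated."""


class ConfigError(FQRSError):
    """Invalid pipeline configuration."""
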