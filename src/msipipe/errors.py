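"""Exception hierarchy for msipipe.

``ValidationError`` subclasses signal bad user input (CLI exit code 3);
everything else under ``PipelineError`` is a runtime failure (exit code 4).
"""


class PipelineError(Exception):
    """Base class for all msipipe errors."""


class ValidationError(PipelineError):
    """Invalid user-supplied data (malformed files, broken invariants)."""


class PanelError(ValidationError):
    """Marker panel fails its invariants or cannot be parsed."""


class FastqFormatError(ValidationError):
    """Unreadable FASTQ input."""


class SpectraFormatError(ValidationError):
    """Malformed allele-spectrum TSV."""


class IhcFormatError(ValidationError):
    """Malformed IHC status table."""


class ConfigError(ValidationError):
    """Invalid simulation or run configuration."""


class TrainingError(PipelineError):
    """Classifier training preconditions not met."""


class ScoringError(PipelineError):
    """Model cannot score the supplied features."""


class ModelIOError(PipelineError):
    """Model file missing, truncated, or schema-incompatible."""


class StatsError(PipelineError):
    """Statistical routine called outside its domain."""
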