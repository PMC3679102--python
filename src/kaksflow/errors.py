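"""Exception hierarchy used across the pipeline."""


class KaksflowError(Exception):
    """Base class for all package errors."""


class FormatError(KaksflowError):
    """Malformed input file (FASTA/FASTQ/TSV structure)."""


class ValidationError(KaksflowError):
    """Well-formed input violating a domain invariant (duplicate ids, bad alphabet...)."""


class ParameterError(KaksflowError):
    """Out-of-range or inconsistent user parameter."""


class ConfigurationError(KaksflowError):
    """Unknown schema / bad pipeline configuration."""


class EstimationError(KaksflowError):
    """A statistic cannot be computed from the given input (e.g. empty alignment)."""
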