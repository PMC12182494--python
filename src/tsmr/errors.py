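"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command-line layer:
validation/format problems -> 2, an empty instrument set -> 3,
estimation failures -> 4.
"""


class TsmrError(Exception):
    """Base class for all package errors."""


class ValidationError(TsmrError):
    """A record or table violates an invariant (bad allele, se <= 0, ...)."""


class FormatError(ValidationError):
    """A file cannot be parsed into the expected schema (missing column,
    non-square LD matrix, mismatched labels)."""


class ClumpError(TsmrError):
    """Instrument selection failed, e.g. a SNP is absent from the LD matrix."""


class HarmonizationError(TsmrError):
    """Harmonization cannot proceed (duplicate variant identifiers)."""


class NoInstrumentsError(TsmrError):
    """No instruments survive selection/harmonization; estimation is impossible."""


class EstimationError(TsmrError):
    """An estimator's preconditions are not met (too few SNPs, zero exposure
    effect, unstable bootstrap configuration)."""
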