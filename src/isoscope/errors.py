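"""Exception hierarchy shared across the package."""


class IsoscopeError(Exception):
    """Base class for all package-specific errors."""


class UsageError(IsoscopeError):
    """Bad user input (empty query, unknown format, unknown config key)."""


class GenePredParseError(IsoscopeError):
    """Malformed genePred row; message names the offending line number."""


class ModelValidationError(IsoscopeError):
    """A transcript/gene structure violates its invariants."""


class ValidationError(IsoscopeError):
    """Cross-table consistency failure (unmapped samples, missing summaries...)."""


class LookupError_(IsoscopeError):
    """Unknown gene, transcript or chromosome."""


class DomainError(IsoscopeError):
    """Operation called outside its mathematical domain (empty vector, negative TPM...)."""


class EligibilityError(IsoscopeError):
    """Cohort does not meet the screening preconditions (e.g. too few normals)."""


class ReferenceMismatchError(IsoscopeError):
    """VCF REF allele disagrees with the genome sequence at that position."""


class GenerationError(IsoscopeError):
    """Synthetic fixture design is infeasible."""
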