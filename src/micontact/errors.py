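"""Exception hierarchy.

Every distinct failure mode named in the module contracts gets its own
class so callers can catch precisely; all inherit from MicontactError.
"""


class MicontactError(Exception):
    """Base class for all package errors."""


class MissingReferenceError(MicontactError):
    """The named reference sequence is not present in the alignment."""


class RaggedAlignmentError(MicontactError):
    """Sequences in the alignment do not all share the same length."""


class DomainRangeError(MicontactError):
    """A domain residue range does not map onto the reference sequence."""


class UnknownSymbolError(MicontactError):
    """A residue symbol has no entry in the alphabet map (sanitize skipped)."""


class EmptyColumnError(MicontactError):
    """An entropy was requested for a column with no observations."""


class ColumnLengthMismatchError(MicontactError):
    """Joint statistics requested for columns of different length."""


class IneligibleColumnError(MicontactError):
    """A score was requested for a column the mask excludes."""


class DegenerateStandardizationError(MicontactError):
    """Standardisation impossible: fewer than two values or zero spread."""


class NoSurvivingPairsError(MicontactError):
    """Every candidate column pair (or triple) was excluded."""


class ZeroMeanError(MicontactError):
    """A mean used as a normaliser (APC / CPS) is zero."""


class SubsampleError(MicontactError):
    """Subsampling parameters leave fewer than two sequences."""


class MissingAnnotationError(MicontactError):
    """A residue lacks an accessibility record or column mapping."""


class StabilityGateError(MicontactError):
    """Alignment is below the minimum sequence count for stability analysis."""


class InconsistentSpecError(MicontactError):
    """A synthetic-data specification contradicts itself."""


class EvaluationError(MicontactError):
    """Evaluation impossible (single-class labels, unreachable recall, ...)."""
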