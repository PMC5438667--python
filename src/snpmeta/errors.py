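"""Exception hierarchy for snpmeta."""


class SnpMetaError(Exception):
    """Base class for all snpmeta errors."""


class SchemaError(SnpMetaError):
    """Input table is missing a required column or has a malformed header."""


class ValidationError(SnpMetaError):
    """A study record violates a structural constraint (negative count,
    unknown category label, duplicate id, empty group...)."""


class InsufficientStudiesError(SnpMetaError):
    """An operation needs more studies than the set provides."""


class UndefinedEffectError(SnpMetaError):
    """The odds ratio of a 2x2 table is undefined even after continuity
    correction (e.g. no exposed individuals in either group)."""


class DegenerateDesignError(SnpMetaError):
    """A meta-regression design matrix is unusable (single observed level,
    collinear moderators)."""
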