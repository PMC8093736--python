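"""Exception hierarchy shared by all dietscope modules."""


class DietscopeError(Exception):
    """Base class for every error raised by dietscope."""


class SchemaError(DietscopeError):
    """A required column is missing or the header is malformed."""


class VocabularyError(DietscopeError):
    """A prey-category code outside the closed vocabulary was encountered."""


class ValidationError(DietscopeError):
    """A row or field violates a domain invariant (range, sign, ordering)."""


class EmptyInputError(DietscopeError):
    """An operation received no usable records."""


class UnknownPopulationError(DietscopeError, KeyError):
    """A population id was requested that is not present in the table."""


class InsufficientDataError(DietscopeError):
    """Too few populations, pairs, or observations for the requested analysis."""


class DegenerateResponseError(DietscopeError):
    """A model response is constant (all present/absent or zero variance)."""


class UndefinedOverlapError(DietscopeError):
    """Overlap requested against a population with no counted prey."""


class ParameterError(DietscopeError):
    """A scenario or configuration parameter is outside its valid range."""


class CompletenessError(DietscopeError):
    """Missing cells where a complete matrix is required (no imputation)."""
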