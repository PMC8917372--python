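"""Exception hierarchy shared across the package."""


class NurseLaborError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NurseLaborError):
    """Invalid configuration: bad distributions, unknown fields, bad options."""


class SchemaError(NurseLaborError):
    """Microdata does not conform to the documented column schema."""


class DomainError(NurseLaborError):
    """An operation was applied outside its mathematical/record domain
    (e.g. classifying a non-economically-active record, empty estimation
    domain, out-of-range year)."""


class ValidationError(NurseLaborError):
    """A value violates a field-level constraint (negative hours, score
    outside 0-5, ...)."""


class SeparationError(NurseLaborError):
    """Perfect separation or a degenerate outcome in a logistic fit."""

    def __init__(self, message: str, terms=None):
        super().__init__(message)
        self.terms = list(terms) if terms is not None else []


class ConvergenceError(NurseLaborError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []
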