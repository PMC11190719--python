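"""Exception hierarchy shared across the package."""


class LymphoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LymphoError, ValueError):
    """An invalid configuration field; the message names the field."""


class SchemaError(LymphoError, ValueError):
    """An input table is missing columns or contains unparseable rows."""


class BaselineMissingError(LymphoError):
    """No blood count eligible as baseline (within 91 days before RT and
    not later than day 2)."""


class DomainError(LymphoError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class AnalysisError(LymphoError, ValueError):
    """A statistical routine cannot run on the provided table
    (rank deficiency, single-level factor, too few rows)."""


class ValidationFailure(LymphoError):
    """A DVH record failed structural validation during a pipeline stage."""
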