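"""Exception hierarchy shared across the pipeline stages."""


class EconsultCbaError(Exception):
    """Base class for all package errors."""


class DomainError(EconsultCbaError, ValueError):
    """An argument violates a mathematical precondition (negative fee, empty sample...)."""


class ConfigurationError(EconsultCbaError):
    """A schedule, config file, or spec is missing a required entry."""


class SpecialtyLookupError(EconsultCbaError, KeyError):
    """A specialty is absent from a fee mapping."""


class ValidationError(EconsultCbaError, ValueError):
    """A record carries an out-of-range or inconsistent value."""
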