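"""Exception hierarchy shared across the package."""


class PMHIAError(Exception):
    """Base class for all pmhia errors."""


class InputFormatError(PMHIAError, ValueError):
    """Raised when an input file cannot be parsed (names the offending row)."""


class ValidationError(PMHIAError, ValueError):
    """Raised when data violate a domain invariant (e.g. duplicate timestamps)."""


class ConfigurationError(PMHIAError, ValueError):
    """Raised on broken cross-references or missing entries in a config."""


class ParameterError(PMHIAError, ValueError):
    """Raised when a user-supplied parameter is outside its valid range."""


class EmptyInputError(PMHIAError, ValueError):
    """Raised when an operation requires non-empty input."""


class CollinearityError(PMHIAError, ValueError):
    """Raised when a regression design matrix is rank deficient."""
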