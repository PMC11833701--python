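"""Exception types shared across the package."""


class MeioquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MeioquantError, ValueError):
    """Raised when input data violate a documented precondition."""


class InvalidParameterError(MeioquantError, ValueError):
    """Raised when a tuning parameter is outside its valid range."""


class InsufficientDataError(MeioquantError, ValueError):
    """Raised when too few observations are available for an estimate."""
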