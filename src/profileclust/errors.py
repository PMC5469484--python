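"""Exception hierarchy shared across the package."""


class ProfileClustError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ProfileClustError, ValueError):
    """A file did not conform to the expected dialect."""


class ValidationError(ProfileClustError, ValueError):
    """Inputs violated a documented precondition or invariant."""


class NumericError(ProfileClustError, ArithmeticError):
    """A numerical routine failed (e.g. singular covariance)."""


class GenerationError(ProfileClustError, RuntimeError):
    """The synthetic-data generator could not satisfy its constraints."""
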