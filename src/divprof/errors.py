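"""Exception hierarchy used across the package."""


class DivprofError(Exception):
    """Base class for all package errors."""


class FormatError(DivprofError):
    """A file does not conform to the expected layout (missing column, bad token)."""


class ValidationError(DivprofError):
    """Input values violate a documented precondition or invariant."""
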