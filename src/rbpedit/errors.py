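"""Exception hierarchy."""


class RbpeditError(Exception):
    """Base class for all package errors."""


class FormatError(RbpeditError):
    """A file could not be parsed or its format was not recognized."""


class ValidationError(RbpeditError):
    """Input values violate a documented contract."""
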