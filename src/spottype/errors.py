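"""Exception types shared across the package."""


class SpotTypeError(Exception):
    """Base class for all package errors."""


class FormatError(SpotTypeError, ValueError):
    """An input file is malformed (bad column, non-numeric cell, duplicate label)."""


class ValidationError(SpotTypeError, ValueError):
    """Inputs are well-formed but violate a precondition of an operation."""
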