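"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2 (bad input / precondition violated),
everything else non-zero maps to exit code 1.
"""


class LipidfingerError(Exception):
    """Base class for package errors."""


class ValidationError(LipidfingerError, ValueError):
    """Input violates a documented precondition."""


class CalibrationError(ValidationError):
    """Lock-mass matching or model fitting failed."""
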