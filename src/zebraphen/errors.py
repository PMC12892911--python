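"""Exception hierarchy.

Readers and validators reject malformed input rather than repairing it;
every error message carries enough provenance (row, column, well id) to
locate the offending record.
"""


class ZebraphenError(Exception):
    """Base class for all package errors."""


class FormatError(ZebraphenError):
    """A file does not conform to the expected tabular format."""


class DataValidationError(ZebraphenError):
    """Well-formed input that violates a semantic invariant."""


class ProtocolMismatchError(DataValidationError):
    """Trace length or structure inconsistent with the stimulus protocol."""


class InsufficientDataError(DataValidationError):
    """Too few observations for the requested computation."""
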