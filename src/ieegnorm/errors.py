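"""Exception hierarchy.

``ValidationError`` marks bad parameters or malformed metadata (CLI exit
code 2); ``DataError`` marks inputs that parse but cannot be analysed
(CLI exit code 3).
"""


class IeegnormError(Exception):
    """Base class for all package errors."""


class ValidationError(IeegnormError):
    """Invalid parameters, schema mismatch or malformed configuration."""


class DataError(IeegnormError):
    """Structurally valid input that cannot be analysed (e.g. zero
    channels remaining after exclusion, degenerate signals)."""
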