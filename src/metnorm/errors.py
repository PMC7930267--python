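"""Exception hierarchy shared across the pipeline.

``ValidationError`` marks inputs that parse but violate a contract
(negative counts, duplicate genes, empty groups); ``FormatError`` marks
files that cannot be parsed at all.  The CLI maps them to exit codes
2 and 3 respectively.
"""


class MetnormError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MetnormError):
    """Input parsed but violates a declared invariant."""


class FormatError(MetnormError):
    """Input file does not conform to the expected format."""
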