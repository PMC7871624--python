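"""Exception hierarchy shared across the package.

The split mirrors how errors surface on the command line: parameter misuse,
invalid data, and I/O failure map to distinct exit codes.
"""


class QuodError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(QuodError):
    """A function argument is outside its legal domain."""


class ValidationError(QuodError):
    """Input data violates an invariant (negative coverage, duplicate ids, ...)."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending location."""


class InputError(QuodError):
    """A required input is missing or unreadable / an output is unwritable."""
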