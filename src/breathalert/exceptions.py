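"""Exception hierarchy.

``ContractError`` and its subclasses signal caller mistakes (bad
parameters, misaligned inputs, malformed files) and map to CLI exit
code 2; plain I/O failures (``OSError``) map to exit code 3.
"""


class BreathAlertError(Exception):
    """Base class for all package-specific errors."""


class ContractError(BreathAlertError):
    """A precondition on an operation's inputs was violated."""


class ParameterError(ContractError):
    """A configuration value is outside its legal range."""


class AlignmentError(ContractError):
    """Two series that must be aligned differ in length or window spec."""


class TraceFormatError(ContractError):
    """A trace file is structurally invalid (e.g. missing sample column)."""


class TraceParseError(TraceFormatError):
    """A trace file contains an unparseable value; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row
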