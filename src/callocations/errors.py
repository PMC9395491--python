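"""Exception hierarchy for the callocations package."""


class CallocationsError(Exception):
    """Base class for all errors raised by this package."""


class RepertoireError(CallocationsError):
    """Invalid repertoire definition (empty, duplicate or blank labels)."""


class UnknownLabelError(CallocationsError):
    """A corpus token uses a label outside the declared repertoire."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"unknown call label: {label!r} is not in the declared repertoire")


class ParseError(CallocationsError):
    """A delimited input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SpecError(CallocationsError):
    """Invalid synthetic-corpus specification."""


class AnalysisError(CallocationsError):
    """A collocation statistic was requested for an unscorable pair."""
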