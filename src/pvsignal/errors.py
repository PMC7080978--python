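"""Exception hierarchy for pvsignal."""


class PvSignalError(Exception):
    """Base class for all package errors."""


class FormatError(PvSignalError):
    """Raised when an input file cannot be parsed in the requested dialect."""


class RecordValidationError(PvSignalError):
    """Raised when a record violates a domain invariant.

    Carries the offending ``report_id`` (when known) and a per-line error
    list for batch reads.
    """

    def __init__(self, message: str, report_id: str | None = None,
                 line_errors: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.report_id = report_id
        self.line_errors = line_errors or []


class DictionaryLookupError(PvSignalError, LookupError):
    """Raised when an SMQ or drug-event pair is absent from a dictionary/config."""


class EstimateUndefinedError(PvSignalError):
    """Raised when a disproportionality estimate is undefined for a table
    (e.g. a zero cell with no continuity correction)."""
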