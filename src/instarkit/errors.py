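"""Exception hierarchy.

All package-specific failures derive from :class:`InstarkitError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class InstarkitError(Exception):
    """Base class for all instarkit errors."""


class TableParseError(InstarkitError):
    """A delimited-text table could not be parsed.

    Carries enough context (row, column) to locate the offending cell.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class ValidationError(InstarkitError):
    """Invalid configuration or arguments; lists every violation."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class InsufficientDataError(InstarkitError):
    """Too few usable values for the requested operation."""


class EmptySummaryError(InstarkitError):
    """A range summary was requested over zero usable values."""
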