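"""Exception hierarchy.

Every error raised by elnkit derives from :class:`ElnError` so callers
(and the CLI) can separate data errors from programming errors.
"""


class ElnError(Exception):
    """Base class for all elnkit errors."""


class MolfileError(ElnError):
    """Malformed or unsupported connection-table input.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CapacityError(ElnError):
    """Input exceeds a hard format limit (e.g. >999 atoms in V2000)."""


class UnknownElementError(ElnError, KeyError):
    """Element symbol absent from the shipped periodic-data tables."""


class BackendError(ElnError):
    """A delegated toolkit backend is unavailable or failed."""


class ValidationError(ElnError):
    """A field value violates its documented domain."""


class IntegrityError(ElnError):
    """An operation would break a cross-record invariant."""


class InsufficientDataError(ElnError):
    """A calculation is requested but a required input is missing."""

    def __init__(self, message: str, missing: str | None = None):
        self.missing = missing
        super().__init__(message)


class MissingReferenceError(ElnError):
    """No reference material is set and none can be defaulted."""


class PermissionDeniedError(ElnError):
    """Actor lacks the permission level required for the action."""


class SnapshotFrozenError(ElnError):
    """Attempt to change the element set of a shared snapshot."""


class NotFoundError(ElnError):
    """Lookup by id, label, code or name matched nothing."""
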