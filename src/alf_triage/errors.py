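"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`AlfTriageError`, so
callers (including the CLI) can distinguish domain failures from bugs.
"""

from __future__ import annotations


class AlfTriageError(Exception):
    """Base class for all errors raised by alf-triage."""


class ValidationError(AlfTriageError):
    """A record or feature set violates a schema invariant.

    Parameters
    ----------
    message:
        Human-readable description of the violated invariant.
    field:
        Name of the offending field, when known.
    patient_id:
        Identifier of the offending record, when known.
    row:
        1-based data-row number in the source file, when known.
    """

    def __init__(self, message: str, *, field: str | None = None,
                 patient_id: str | None = None, row: int | None = None):
        self.field = field
        self.patient_id = patient_id
        self.row = row
        prefix = []
        if row is not None:
            prefix.append(f"row {row}")
        if patient_id is not None:
            prefix.append(f"patient {patient_id!r}")
        if field is not None:
            prefix.append(f"field {field!r}")
        if prefix:
            message = f"[{', '.join(prefix)}] {message}"
        super().__init__(message)


class MissingDataError(AlfTriageError):
    """An operation requires values that are absent; no imputation is done."""

    def __init__(self, message: str, *, missing: list[str] | None = None,
                 patient_id: str | None = None):
        self.missing = missing or []
        self.patient_id = patient_id
        if self.missing:
            message = f"{message} (missing: {', '.join(self.missing)})"
        if patient_id is not None:
            message = f"[patient {patient_id!r}] {message}"
        super().__init__(message)


class ParseError(AlfTriageError):
    """A record file could not be parsed; names the offending line."""


class AlignmentError(AlfTriageError):
    """Two parallel sequences (records vs diagnoses, predictions vs
    observations) do not have matching lengths."""


class PreconditionError(AlfTriageError):
    """An operation was called outside its documented domain, e.g. the
    transplant guideline on a patient without grade >= II encephalopathy."""


class ConfigError(AlfTriageError):
    """A configuration value is out of its documented range or infeasible."""
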