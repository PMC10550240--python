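"""Exception hierarchy shared across the package.

Validation errors signal bad user input (CLI exit code 2); stage errors
signal a failure inside a workflow stage (CLI exit code 3).
"""


class SecgateError(Exception):
    """Base class for all package errors."""


class ValidationError(SecgateError, ValueError):
    """Invalid input or configuration."""


class AnchorNotFoundError(ValidationError):
    """A required anchor motif could not be located in a sequence.

    ``side`` is ``"left"`` or ``"right"``.
    """

    def __init__(self, message: str, side: str):
        super().__init__(message)
        self.side = side


class StageError(SecgateError, RuntimeError):
    """A workflow stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str, record_id: str | None = None):
        detail = f"[{stage}] {message}"
        if record_id is not None:
            detail += f" (record: {record_id})"
        super().__init__(detail)
        self.stage = stage
        self.record_id = record_id
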