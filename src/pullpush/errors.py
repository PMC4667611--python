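"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4. ``StageError`` wraps a failure with the stage name and
frame index so end-to-end runs report where they died.
"""


class PullPushError(Exception):
    """Base class for all package errors."""


class ConfigError(PullPushError):
    """Invalid or inconsistent configuration."""


class DataError(PullPushError):
    """Malformed, irregular or unreadable input data."""


class NumericalError(PullPushError):
    """A computation could not produce a usable result."""


class StageError(PullPushError):
    """Error raised inside a pipeline stage, annotated with context."""

    def __init__(self, stage: str, frame: int | None, cause: Exception):
        self.stage = stage
        self.frame = frame
        self.cause = cause
        where = f"stage '{stage}'" + (f", frame {frame}" if frame is not None else "")
        super().__init__(f"{where}: {cause}")
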