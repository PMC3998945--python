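"""Exception hierarchy."""


class NetQueryError(Exception):
    """Base class for all netquery errors."""


class FormatError(NetQueryError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        if path is not None and line is not None:
            message = f"{path}:{line}: {message}"
        elif path is not None:
            message = f"{path}: {message}"
        super().__init__(message)
        self.path = path
        self.line = line


class PipelineError(NetQueryError):
    """A pipeline stage failed; names the stage and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
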