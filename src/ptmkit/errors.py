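"""Exception hierarchy.

All library errors derive from :class:`PtmkitError` so callers (and the CLI)
can distinguish data problems (exit code 1) from usage problems (exit code 2).
"""


class PtmkitError(Exception):
    """Base class for all ptmkit errors."""


class FormatError(PtmkitError):
    """A file does not conform to its declared format (e.g. missing column)."""


class RowError(FormatError):
    """A single data row is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class UsageError(PtmkitError):
    """The caller asked for something the API does not offer (bad dialect, sort key...)."""


class DialectAmbiguityError(UsageError):
    """A table's header matches zero or several known dialects."""

    def __init__(self, message: str, candidates: list[str]):
        super().__init__(message)
        self.candidates = candidates


class UnfilterableError(PtmkitError):
    """FDR filtering was requested but neither scores nor q-values are available."""


class IntegrityError(PtmkitError):
    """A session file is corrupt, truncated or otherwise unreadable."""


class VersionError(IntegrityError):
    """A session file was written by an incompatible format version."""


class PipelineError(PtmkitError):
    """An error propagated from a pipeline stage; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.__cause__ = cause
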