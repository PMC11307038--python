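"""Exception hierarchy for the pipeline."""


class MirseparateError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(MirseparateError):
    """Invalid simulation or run configuration."""


class ParseError(MirseparateError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateWellError(MirseparateError):
    """Duplicate (sample, assay) well within a plate."""


class CalibrationError(MirseparateError):
    """Interplate calibration impossible (e.g. no detected UniSpike 3 wells)."""


class EmptyPanelError(MirseparateError):
    """Every feature was removed by censoring / retention filters."""


class NoReferenceError(MirseparateError):
    """A miRNA has no detected value in the reference group."""


class DegenerateInputError(MirseparateError):
    """Input carries no usable variance / structure for the requested fit."""


class PipelineStageError(MirseparateError):
    """A pipeline stage failed; names the stage and keeps the cause chained."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")

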