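"""Exception hierarchy for the prioritization pipeline."""


class SczprioError(Exception):
    """Base class for all package errors."""


class ValidationError(SczprioError, ValueError):
    """A value violates a documented invariant (range, consistency, uniqueness)."""


class FormatError(ValidationError):
    """An input file does not match the expected tabular schema."""


class ParameterError(SczprioError, ValueError):
    """Infeasible or out-of-range parameters for a generator or test."""


class PipelineStageError(SczprioError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
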