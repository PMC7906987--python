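"""Exception hierarchy for the crosstalk pipeline."""


class CrosstalkError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CrosstalkError):
    """A configuration value is outside its valid range or malformed."""


class DataValidationError(CrosstalkError):
    """An input matrix, metadata table, or dataset violates a contract."""


class DegenerateDataError(CrosstalkError):
    """A statistic is undefined on the given input (e.g. zero pooled SD)."""


class StageError(CrosstalkError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
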