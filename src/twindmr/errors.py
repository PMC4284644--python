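"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto process exit codes: configuration errors exit 2,
data errors exit 3, and stage failures exit 4.
"""


class TwindmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TwindmrError):
    """Invalid configuration value, unknown key, or inconsistent settings."""


class DataError(TwindmrError):
    """Malformed or inconsistent input data (matrices, tables, intervals)."""


class ModelError(TwindmrError):
    """Statistical model cannot be fitted (rank deficiency, collinearity...)."""


class StageError(TwindmrError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
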