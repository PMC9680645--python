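"""Exception hierarchy shared across pipeline stages."""


class FinphenoError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FinphenoError):
    """A statement file cannot be interpreted under the given dialect."""


class RangeError(FinphenoError):
    """A date falls outside the span covered by the life chart."""


class InsufficientDataError(FinphenoError):
    """Too few observations to form the requested statistic."""


class UndefinedStatisticError(FinphenoError):
    """The statistic is mathematically undefined on this input (e.g. tau = 0)."""


class DegenerateVarianceError(FinphenoError):
    """A group has zero variance; heteroscedastic inference is undefined."""


class ConfigError(FinphenoError):
    """Invalid or inconsistent configuration."""


class PipelineStageError(FinphenoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
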