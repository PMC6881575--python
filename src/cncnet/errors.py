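"""Exception hierarchy shared across the pipeline."""


class CncnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CncnetError):
    """A simulation or pipeline configuration is invalid or infeasible."""


class DomainError(CncnetError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class DegenerateInputError(DomainError):
    """Input is formally valid but the statistic is undefined on it
    (e.g. zero pooled variance with unequal means)."""


class FormatError(CncnetError):
    """A file does not conform to the expected on-disk format."""


class PipelineError(CncnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
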