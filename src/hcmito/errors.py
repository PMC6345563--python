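"""Exception hierarchy for the hcmito pipeline.

Every stage raises a subclass of :class:`PipelineError` so the CLI can
attach a stage tag and exit nonzero without a traceback.
"""


class PipelineError(Exception):
    """Base class for all hcmito errors."""


class ConfigError(PipelineError):
    """Invalid configuration value or inconsistent parameter combination."""


class InvalidBaselineError(PipelineError):
    """Baseline fluorescence F0 is non-positive; the trace cannot be normalized."""


class UndefinedResponseError(PipelineError):
    """No positive response (peak <= baseline); rise time is undefined."""


class UndefinedRatioError(PipelineError):
    """Green-channel mean is non-positive; the red:green ratio is undefined."""


class GenerationError(PipelineError):
    """Synthetic-data generation could not satisfy a geometric constraint."""


class StageError(PipelineError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
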