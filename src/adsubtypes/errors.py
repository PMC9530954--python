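"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """A data file violates the expected tab-delimited/GMT contract."""


class ConfigError(ValueError):
    """A configuration (cohort or pipeline) is invalid or incomplete."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
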