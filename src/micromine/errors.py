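"""Exception hierarchy for the pipeline."""


class MicromineError(Exception):
    """Base class for all package errors."""


class FastaParseError(MicromineError):
    """Malformed FASTA input; message names the offending line."""


class ConfigError(MicromineError):
    """Invalid pipeline configuration."""


class StageError(MicromineError):
    """A pipeline stage failed; message names the stage and input id."""

    def __init__(self, stage: str, input_id: str, message: str):
        self.stage = stage
        self.input_id = input_id
        super().__init__(f"stage {stage!r} failed on input {input_id!r}: {message}")
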