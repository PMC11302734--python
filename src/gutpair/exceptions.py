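"""Exception types shared across the pipeline."""


class GutpairError(Exception):
    """Base class for all package errors."""


class ValidationError(GutpairError, ValueError):
    """Raised when data violate a type invariant (negative abundance, unpaired metadata ...)."""


class ConfigurationError(GutpairError, ValueError):
    """Raised when a simulation or pipeline configuration is internally inconsistent."""


class ParseError(GutpairError, ValueError):
    """Raised when an input file cannot be parsed; carries file/line context in the message."""


class PipelineError(GutpairError, RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
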