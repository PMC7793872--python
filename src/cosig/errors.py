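"""Exception hierarchy shared across the pipeline stages."""


class CosigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CosigError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(CosigError):
    """A malformed input file.

    Parameters
    ----------
    message:
        Human-readable description of the defect.
    line:
        1-based line number in the offending file, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(CosigError):
    """Inputs that are individually valid but mutually inconsistent."""


class DegenerateSampleError(CosigError):
    """A sample that cannot be normalized (zero library size / no nonzero counts)."""


class DegenerateInputError(CosigError):
    """An input matrix on which the requested decomposition is undefined."""


class PipelineError(CosigError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
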