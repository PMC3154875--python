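"""Exception hierarchy shared across the pipeline."""


class TetraSnpError(Exception):
    """Base class for all errors raised by tetrasnp."""


class ConfigurationError(TetraSnpError):
    """A configuration value is missing, malformed, or inconsistent."""


class InputError(TetraSnpError):
    """An input record or argument violates a documented precondition."""


class AceParseError(TetraSnpError):
    """Malformed ACE assembly file.

    Carries the 1-based line number where parsing failed.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PslParseError(TetraSnpError):
    """Malformed PSL alignment file (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PipelineError(TetraSnpError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
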