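"""Exception hierarchy."""


class SrsSignalError(Exception):
    """Base class for package errors."""


class ConfigError(SrsSignalError):
    """Invalid configuration; the message names the offending field."""


class SchemaError(SrsSignalError):
    """Input file missing a required column or header."""


class ValidationError(SrsSignalError):
    """A loaded term set / panel violates its invariants."""


class DegenerateInputError(SrsSignalError):
    """An operation received input it is mathematically undefined on."""


class StageError(SrsSignalError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
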