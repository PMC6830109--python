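"""Exception hierarchy shared across the package."""


class RetroscanError(Exception):
    """Base class for all retroscan errors."""


class ParseError(RetroscanError):
    """A line of an input file could not be parsed."""


class FormatError(RetroscanError):
    """An input file is not in any recognized dialect."""


class DataError(RetroscanError):
    """Inputs are well-formed but internally inconsistent."""


class ConfigError(RetroscanError):
    """A configuration value violates its invariants."""


class PipelineError(RetroscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
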