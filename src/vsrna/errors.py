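"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is infeasible or inconsistent.

    The message names the offending field so a config file can be fixed
    without reading the traceback.
    """


class FormatError(ValueError):
    """An input file violates its format; carries the 1-based line/record number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
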