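"""Exception hierarchy shared across the package."""


class SezconnError(Exception):
    """Base class for all package errors."""


class ParseError(SezconnError):
    """A flat-file export could not be parsed.

    Carries the path and 1-based line number of the first offending line
    where available.
    """

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:"
            if line is not None:
                prefix += f"{line}:"
            prefix += " "
        super().__init__(prefix + message)


class ConfigError(SezconnError):
    """A run configuration failed validation before any computation."""


class PipelineError(SezconnError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
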