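"""Exception hierarchy for the netpharm pipeline."""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NetpharmError):
    """A tabular input is missing a required column or has a malformed header."""


class ParseError(NetpharmError):
    """A row or line of an input file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class MappingConflictError(NetpharmError):
    """A raw protein name maps to more than one official gene symbol."""


class EmptyIntersectionError(NetpharmError):
    """The herb-target / disease-gene intersection is empty; downstream stages are undefined."""


class PipelineError(NetpharmError):
    """A pipeline stage failed; partial artifacts may have been retained."""
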