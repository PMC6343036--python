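"""Exception types shared across the package."""


class HrscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HrscanError):
    """Invalid configuration or parameter value."""


class FormatError(HrscanError):
    """Malformed input file; carries a line number when known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class MissingDataError(HrscanError):
    """A required record (strain, pair, gene) is absent from the input."""


class UndefinedStatisticError(HrscanError):
    """The requested quantity is undefined on this input (e.g. ANIb of an empty set)."""
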