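"""Exception hierarchy.

Exit-code mapping used by the CLI: validation problems (bad input data or
configuration) exit 1, internal errors exit 2.
"""


class PdxEvoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PdxEvoError):
    """A parameter combination or name that the pipeline cannot honor."""


class ValidationError(PdxEvoError):
    """Malformed input data; carries enough context to locate the record."""

    def __init__(self, message: str, *, record=None, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.record = record
        self.line = line


class DegenerateDataError(PdxEvoError):
    """A quantity is undefined on the given input (empty union, zero variance...)."""
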