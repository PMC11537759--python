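"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ``ConfigurationError`` and
``ValidationError`` exit 2 (bad inputs/configuration), ``DataError`` and
its subclasses exit 3 (problems in the data files themselves).
"""


class CallSeqError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CallSeqError):
    """A configuration value or column mapping is invalid or missing."""


class ValidationError(CallSeqError):
    """Input data violate a documented invariant (e.g. offset < onset)."""


class DataError(CallSeqError):
    """A data file cannot be read or parsed."""


class ParseError(DataError):
    """A field in a data file cannot be parsed (carries the row number)."""
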