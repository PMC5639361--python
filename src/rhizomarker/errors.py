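"""Exception hierarchy shared across the package.

CLI exit codes: ConfigError -> 2, data-level errors (FormatError,
ValidationError) -> 3.
"""


class RhizomarkerError(Exception):
    """Base class for all package errors."""


class FormatError(RhizomarkerError):
    """A file does not follow the expected tabular layout."""


class ValidationError(RhizomarkerError):
    """Contents parsed but violate a domain invariant."""


class ConfigError(RhizomarkerError):
    """Invalid configuration or parameter combination."""
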