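"""Exception hierarchy.

``DataError`` maps to CLI exit code 1 (malformed or inconsistent input
data), ``ConfigError`` to exit code 2 (bad parameters or configuration).
"""


class ToxDeconvError(Exception):
    """Base class for all package-specific errors."""


class DataError(ToxDeconvError, ValueError):
    """Invalid or inconsistent input data."""


class ConfigError(ToxDeconvError, ValueError):
    """Invalid configuration or parameter values."""
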