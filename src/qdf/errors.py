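"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config errors -> 2, data errors -> 3).
"""


class QdfError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(QdfError):
    """Invalid configuration (bad parameter values, unresolvable paths)."""


class DataError(QdfError):
    """Invalid or inconsistent input data (shape mismatches, missing files)."""
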