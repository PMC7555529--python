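"""Exception hierarchy shared across the package.

``ConfigError`` means the request itself is invalid (bad thresholds,
impossible constitution spec); ``DataError`` means the inputs are malformed
or insufficient (unparseable table, too few loci).  The CLI maps them to
exit codes 2 and 3 respectively.
"""


class MoleKaryoError(Exception):
    """Base class for package errors."""


class ConfigError(MoleKaryoError):
    """Invalid configuration or constitution specification."""

    exit_code = 2


class DataError(MoleKaryoError):
    """Malformed or insufficient input data."""

    exit_code = 3
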