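"""Exception hierarchy mapped to CLI exit codes."""


class GbscallError(Exception):
    """Base class; exit code 1."""

    exit_code = 1


class ConfigError(GbscallError):
    """Invalid configuration or arguments; exit code 2."""

    exit_code = 2


class DataError(GbscallError):
    """Malformed input data or file format; exit code 3."""

    exit_code = 3


class ConsistencyError(GbscallError):
    """Internal bookkeeping violated (counts do not reconcile); exit code 4."""

    exit_code = 4
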