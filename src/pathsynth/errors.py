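"""Typed exceptions mapped to CLI exit codes.

ConfigError -> 2, DataError -> 3, StageError -> 4.
"""


class PathsynthError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PathsynthError):
    """Invalid configuration or parameter values."""

    exit_code = 2


class DataError(PathsynthError):
    """Malformed, inconsistent, or missing input data."""

    exit_code = 3


class StageError(PathsynthError):
    """A pipeline stage failed; the message names the stage."""

    exit_code = 4
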