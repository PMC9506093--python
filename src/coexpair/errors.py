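"""Exception hierarchy shared across the pipeline.

The CLI maps these to exit codes: ConfigError -> 2, FormatError/DataError
-> 3, StageError -> 4.
"""


class CoexpairError(Exception):
    """Base class for all package errors."""


class ConfigError(CoexpairError):
    """Invalid configuration value or violated configuration invariant."""


class FormatError(CoexpairError):
    """Malformed input file (wrong shape, bad header, duplicate labels...)."""


class DataError(CoexpairError):
    """Inputs are well-formed but mutually inconsistent or degenerate."""


class StageError(CoexpairError):
    """A pipeline stage failed; the message names the stage."""
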