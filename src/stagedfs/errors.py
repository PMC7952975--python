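"""Exception hierarchy mapped onto CLI exit codes."""


class StagedFSError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(StagedFSError):
    """Invalid configuration key or out-of-range value."""

    exit_code = 2


class DataFormatError(StagedFSError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class PipelineError(StagedFSError):
    """A pipeline stage cannot proceed (empty survivor set, missing class...)."""

    exit_code = 4
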