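"""Exception types shared across the pipeline."""


class MEScanError(Exception):
    """Base class for all package errors."""


class ConfigError(MEScanError, ValueError):
    """Invalid configuration value or combination."""


class DataError(MEScanError, ValueError):
    """Malformed or inconsistent input data."""


class ParseError(DataError):
    """A record could not be parsed; the message identifies it."""
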