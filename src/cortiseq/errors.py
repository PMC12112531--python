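"""Exception types shared across the pipeline."""


class CortiseqError(Exception):
    """Base class for pipeline errors."""


class ConfigError(CortiseqError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(CortiseqError, ValueError):
    """Malformed or inconsistent input data."""
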