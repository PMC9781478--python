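"""Exception types shared across the pipeline."""


class PulseBPError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PulseBPError, ValueError):
    """A configuration value or function argument is out of range."""


class DegenerateSignalError(PulseBPError, ValueError):
    """A signal cannot be processed (e.g. zero variance where scale is needed)."""


class EmptySessionError(PulseBPError, ValueError):
    """A requested session is too short to contain a single cardiac cycle."""


class InvalidBeatError(PulseBPError, ValueError):
    """A per-beat computation received inconsistent landmark data."""


class SchemaError(PulseBPError, KeyError):
    """An input table is missing variables required by a fitted model."""


class ConfigError(PulseBPError, ValueError):
    """A pipeline configuration file is invalid."""
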