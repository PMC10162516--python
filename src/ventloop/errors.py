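"""Exception hierarchy shared by all ventloop modules."""


class VentloopError(Exception):
    """Base class for every error raised by this package."""


class ConfigError(VentloopError):
    """Invalid configuration value, unknown unit, or malformed config file."""


class SimulationError(VentloopError):
    """The virtual subject reached an infeasible or non-finite state."""


class LoggingError(VentloopError):
    """Run-log contract violation, e.g. a clock regression."""


class SchemaError(VentloopError):
    """A replayed CSV does not match the run-log column schema."""
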