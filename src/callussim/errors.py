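"""Exception types shared across the simulator."""


class CallusSimError(Exception):
    """Base class for all simulator errors."""


class ConfigurationError(CallusSimError):
    """A configuration value is missing, inconsistent or out of range.

    The message names the offending key so that run configs can be fixed
    without reading source code.
    """


class ParameterError(CallusSimError, KeyError):
    """A kinetic rate symbol was requested that is not in the registry."""


class SolverError(CallusSimError):
    """Time integration failed (step-size underflow, NaN state, ...)."""
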