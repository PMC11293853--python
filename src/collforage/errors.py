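"""Exception types raised by the simulator."""


class CollforageError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigurationError(CollforageError, ValueError):
    """A simulation or network configuration violates a model constraint."""


class InitializationInfeasibleError(CollforageError, RuntimeError):
    """No valid group-to-patch assignment exists for a partitioned start."""
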