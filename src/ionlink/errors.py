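"""Exception taxonomy shared across the package."""


class IonlinkError(Exception):
    """Base class for all ionlink errors."""


class InputError(IonlinkError):
    """Malformed or unreadable input data (peak lists, raw files, RT tables)."""


class ConfigurationError(IonlinkError):
    """Invalid configuration: unknown elements, missing columns, bad parameter values."""


class ResourceLimitError(IonlinkError):
    """A combinatorial search exceeded its configured budget."""
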