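"""Exception hierarchy shared across the package."""


class LeafAtacError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LeafAtacError):
    """Input data violates a format or coordinate contract (bad line, bad bounds)."""


class ContractError(LeafAtacError):
    """An API precondition was violated by the caller (e.g. unsorted input)."""


class ConfigError(LeafAtacError):
    """A simulation or analysis configuration is internally inconsistent."""


class SizingError(ConfigError):
    """Requested synthetic genome cannot accommodate the requested features."""
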