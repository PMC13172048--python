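"""Exception hierarchy shared across the package."""


class IfnkitError(Exception):
    """Base class for all ifnkit errors."""


class ConfigError(IfnkitError):
    """Invalid configuration value or combination."""


class ValidationError(IfnkitError):
    """Input data violates a documented precondition."""


class CapacityError(IfnkitError):
    """Requested gene layout does not fit on the simulated chromosome."""


class FormatError(IfnkitError):
    """Malformed record in an input file; message carries the location."""
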