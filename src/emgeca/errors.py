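"""Exception types shared across the package."""


class EmgError(Exception):
    """Base class for all emgeca errors."""


class ValidationError(EmgError, ValueError):
    """An input violated an operation's contract (user error)."""


class ConfigurationError(EmgError, RuntimeError):
    """A configuration is internally inconsistent or infeasible."""
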