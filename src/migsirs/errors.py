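"""Exception types used across the package."""


class MigsirsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MigsirsError, ValueError):
    """A parameter, state, or argument violates a model invariant."""


class IntegrationError(MigsirsError, RuntimeError):
    """The ODE solver failed; carries the offending context in args."""


class ConfigError(MigsirsError):
    """Base class for configuration-file problems."""


class ConfigFileError(ConfigError):
    """The configuration file is missing or unreadable."""


class ConfigSyntaxError(ConfigError):
    """The configuration file is not valid structured text."""


class ConfigValidationError(ConfigError, ValueError):
    """The configuration parsed but violates an invariant or has unknown keys."""
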