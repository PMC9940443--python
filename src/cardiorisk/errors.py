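"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when data handed to an operation violates its preconditions."""


class ConfigurationError(ValueError):
    """Raised when a run is configured in a way that cannot be executed."""
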