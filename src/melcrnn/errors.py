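"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data violates a structural invariant (shape, finiteness, range)."""


class ConfigError(ValueError):
    """A configuration value is invalid or inconsistent with other settings."""
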