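"""Exception types shared across the package."""


class ShapeError(ValueError):
    """An array has the wrong shape for the requested operation."""


class ConfigError(ValueError):
    """A configuration value is out of its allowed domain."""
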