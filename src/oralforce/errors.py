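"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A run configuration, parameter override or input table is inconsistent."""


class DataError(ValueError):
    """An input dataset violates a structural invariant (duplicate ids, unknown codes)."""
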