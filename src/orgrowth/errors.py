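"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid generator or pipeline configuration."""


class SchemaError(ValueError):
    """Tabular input does not match the expected schema."""


class DegenerateNullError(ValueError):
    """A permutation null has zero variance, so z-scores are undefined."""
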