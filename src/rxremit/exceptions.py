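class ConfigurationError(ValueError):
    """Raised when a simulation or study configuration is internally inconsistent."""


class ModelSchemaError(ValueError):
    """Raised when an exported model document does not match the expected schema."""
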