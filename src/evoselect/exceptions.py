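"""Package-level exception types."""


class ConfigurationError(ValueError):
    """Raised when a search space, population or pipeline setting is invalid."""


class EvaluationError(RuntimeError):
    """Raised when a model evaluation cannot be completed."""
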