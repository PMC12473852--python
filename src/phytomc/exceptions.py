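"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A parameter set is inconsistent, incomplete or out of its valid domain."""


class StepSizeError(RuntimeError):
    """An integration step produced an invalid state; the caller must subdivide."""
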