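"""Exception types shared across the pipeline."""


class ToneCortexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ToneCortexError):
    """Invalid generator or pipeline configuration."""


class SchemaError(ToneCortexError):
    """A file or table violates the expected schema."""


class FeatureMismatchError(ToneCortexError):
    """Feature builds are incompatible (e.g. bin edges from different corpora)."""


class MissingToneError(ToneCortexError):
    """Tone labels requested from a stimulus that carries none."""


class PipelineError(ToneCortexError):
    """A pipeline stage is missing an upstream artifact."""
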