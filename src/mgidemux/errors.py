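"""Exception hierarchy. The CLI maps these onto exit codes."""


class MgidemuxError(Exception):
    """Base class for all package errors."""


class ValidationError(MgidemuxError):
    """Input fails a semantic constraint (bad index characters, duplicate
    index pairs, inconsistent lengths...)."""


class FormatError(ValidationError):
    """Input text does not match the expected grammar (sample sheet header,
    MGI read id, template spec string)."""


class ConfigError(MgidemuxError):
    """Inconsistent or incomplete run configuration."""


class MergeError(MgidemuxError):
    """Reports cannot be merged (mismatched sample universes)."""
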