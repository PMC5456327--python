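"""Exception hierarchy shared across the pipeline."""


class FabryMetaError(Exception):
    """Base class for all package errors."""


class FormatError(FabryMetaError, ValueError):
    """A file does not conform to its declared dialect (missing column,
    short line, unknown closed-vocabulary value)."""


class ValidationError(FabryMetaError, ValueError):
    """A record violates a domain invariant (ratio <= 0, p outside [0,1],
    dangling study reference)."""


class ConfigError(FabryMetaError, ValueError):
    """A configuration value is out of its admissible range."""
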