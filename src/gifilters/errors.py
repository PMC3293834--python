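"""Exception hierarchy shared across the toolkit."""


class GIFilterError(Exception):
    """Base class for all toolkit errors."""


class FormatError(GIFilterError):
    """A file does not conform to its declared dialect/schema."""


class ValidationError(GIFilterError, ValueError):
    """Inputs are well-formed but semantically invalid."""


class ConfigurationError(GIFilterError):
    """A run configuration references a missing or inconsistent resource."""
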