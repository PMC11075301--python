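"""Exception hierarchy shared across the package."""


class MenkitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MenkitError):
    """Invalid configuration or parameter value."""


class FormatError(MenkitError):
    """Malformed input table or metadata."""


class AnalysisError(MenkitError):
    """A computation's preconditions are not met by the data."""
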