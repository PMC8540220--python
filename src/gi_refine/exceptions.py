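"""Exception hierarchy."""


class GIRefineError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GIRefineError):
    """A user-supplied configuration value or dialect is invalid."""


class FormatError(GIRefineError):
    """An input file violates its expected format."""


class AlignmentError(GIRefineError):
    """Cell identifiers cannot be aligned across the given sources."""
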