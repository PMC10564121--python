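"""Exception hierarchy shared across the package."""


class PolydevError(Exception):
    """Base class for all errors raised by polydev."""


class FormatError(PolydevError):
    """A file or table does not conform to the expected layout."""


class ConfigError(PolydevError):
    """A configuration value is out of its admissible range."""


class DataError(PolydevError):
    """Input data violate a precondition of an operation."""
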