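"""Exception hierarchy shared across the package."""


class HeteroscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HeteroscanError):
    """A configuration value is out of range or inconsistent."""


class ParseError(HeteroscanError):
    """An input file could not be parsed."""


class FormatError(HeteroscanError):
    """An input file parsed but violates the expected format contract."""


class ValidationError(HeteroscanError):
    """A data container violates one of its invariants."""


class ReferentialIntegrityError(ValidationError):
    """A record references an id that does not exist."""
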