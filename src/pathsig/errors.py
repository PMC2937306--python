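"""Exception hierarchy.

All validation failures derive from :class:`ValidationError` (a ``ValueError``),
so callers can catch a single type; the CLI maps it to exit code 2 and any
other failure to exit code 1.
"""


class PathsigError(Exception):
    """Base class for errors raised by pathsig."""


class ValidationError(PathsigError, ValueError):
    """Invalid inputs, parameters, or data that violates a contract."""


class ConfigurationError(ValidationError):
    """A configuration object or file is invalid; the message names the field."""


class ParseError(ValidationError):
    """A file could not be parsed; the message carries the line number."""
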