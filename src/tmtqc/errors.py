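"""Exception hierarchy for the package."""


class TmtQcError(Exception):
    """Base class for all package errors."""


class ConfigError(TmtQcError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(TmtQcError):
    """Malformed matrix input or inconsistent container state."""


class MetadataError(TmtQcError):
    """Invalid or unparseable sample metadata."""


class QCError(TmtQcError):
    """A QC stage cannot proceed (empty matrix, zero loading total, ...)."""
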