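"""Exception hierarchy shared across the package.

Everything derives from :class:`EMGError` so callers can catch one base;
each subclass also inherits the matching builtin so untargeted ``except
ValueError`` / ``except IOError`` code keeps working.
"""


class EMGError(Exception):
    """Base class for all emgmotion errors."""


class ParseError(EMGError, ValueError):
    """A file could not be parsed (non-numeric cell, corrupt header, ...)."""


class StructureError(EMGError, ValueError):
    """Structurally invalid input (ragged rows, missing channel, ...)."""


class FormatError(EMGError, ValueError):
    """Unsupported file format variant (e.g. mixed EDF sampling rates)."""


class ConfigError(EMGError, ValueError):
    """Invalid configuration value (filter band vs Nyquist, GA ranges, ...)."""


class DomainError(EMGError, ValueError):
    """Input outside an operation's mathematical domain."""


class ValidationError(EMGError, ValueError):
    """Runtime data/model consistency failure (feature width mismatch, ...)."""
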