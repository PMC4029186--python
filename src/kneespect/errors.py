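"""Exception hierarchy shared across the package.

Every error class maps to a distinct CLI exit code (see ``cli.EXIT_CODES``).
"""


class KneeSpectError(Exception):
    """Base class for all package errors."""


class ZoneParseError(KneeSpectError, ValueError):
    """A zone label string violates the label grammar."""


class InvalidZoneError(KneeSpectError, ValueError):
    """A zone is unknown to the scheme or absent from a label map legend."""


class GeometryError(KneeSpectError, ValueError):
    """Degenerate or inconsistent landmark geometry."""


class MissingLandmarkError(KneeSpectError, KeyError):
    """A required landmark (or auxiliary field) is absent; the message names it."""


class BoundsError(KneeSpectError, ValueError):
    """A landmark lies outside the image volume."""


class MissingReferenceError(KneeSpectError, ValueError):
    """The reference zone is empty in the label map."""


class ZeroReferenceError(KneeSpectError, ValueError):
    """The reference-region statistic is not strictly positive."""


class InsufficientDataError(KneeSpectError, ValueError):
    """Too few subjects/raters/pairs for the requested statistic."""


class UndefinedICCError(KneeSpectError, ValueError):
    """Zero total variance: the intraclass correlation is undefined."""


class ConfigError(KneeSpectError, ValueError):
    """Invalid configuration (run config or phantom config)."""


class FormatError(KneeSpectError, ValueError):
    """Unreadable or invalid input file content."""
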