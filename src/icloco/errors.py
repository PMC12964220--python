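"""Exception types shared across the package."""


class ICLocoError(Exception):
    """Base class for all package errors."""


class DegenerateInputError(ICLocoError):
    """Raised when an input is too short/empty for the requested operation."""


class EligibilityError(ICLocoError):
    """A unit or onset does not meet the inclusion rules for an analysis."""


class SessionFormatError(ICLocoError):
    """Base class for session-container I/O problems."""


class MissingFileError(SessionFormatError):
    """A file listed in the session manifest is absent."""


class SchemaVersionError(SessionFormatError):
    """The session manifest declares an unrecognized schema version."""


class RateMismatchError(SessionFormatError):
    """A signal's sidecar metadata disagrees with the manifest."""
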