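"""Exception types shared across the package."""


class GroomctxError(Exception):
    """Base class for package errors."""


class SessionLoadError(GroomctxError):
    """A session directory is missing a required file or is unreadable."""


class SessionValidationError(GroomctxError, ValueError):
    """A session object violates a structural invariant."""


class SchedulingError(GroomctxError):
    """A stimulus schedule cannot fit the configured block durations."""


class InsufficientDataError(GroomctxError):
    """Too few trials/bins/beats to run the requested analysis."""
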