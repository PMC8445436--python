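"""Exception types shared across the package."""

from __future__ import annotations


class VistrainError(Exception):
    """Base class for package errors."""


class InvalidProfileError(VistrainError, ValueError):
    """A device profile is unusable (e.g. non-positive viewing distance)."""


class OutOfFieldError(VistrainError, ValueError):
    """A converted coordinate falls outside the target device's field of view.

    Carries ``clipped``, the coordinate pair clamped onto the field boundary,
    so callers that prefer clamping to raising can recover it.
    """

    def __init__(self, message: str, clipped: tuple[float, float]):
        super().__init__(message)
        self.clipped = clipped


class LogParseError(VistrainError, ValueError):
    """A session log file is malformed; the message names the offending field."""
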