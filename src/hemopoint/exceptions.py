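"""Exception hierarchy.

All package-raised errors derive from :class:`HemopointError`.  User-facing
tooling (the CLI) maps :class:`UserInputError` subclasses to exit code 1 and
anything else to exit code 2.
"""


class HemopointError(Exception):
    """Base class for all errors raised by hemopoint."""


class UserInputError(HemopointError):
    """Errors caused by invalid user input (configs, files, preconditions)."""


class ConfigurationError(UserInputError):
    """Invalid configuration value (unknown template, degenerate range, ...)."""


class GeometryError(UserInputError):
    """Geometrically invalid vessel description (e.g. non-positive throat)."""


class StructuralError(HemopointError):
    """Vessel graph violates a structural invariant (disconnected, bad cycle)."""


class PreconditionError(UserInputError):
    """Operation precondition not met (e.g. grafting a postoperative tree)."""


class OutOfLumenError(UserInputError):
    """A query point lies on or outside the vessel wall."""


class FormatError(UserInputError):
    """Malformed on-disk data. Carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class WeightsFormatError(UserInputError):
    """Weights file is corrupt, truncated, or incompatible with the config."""


class EvaluationError(UserInputError):
    """Error metric undefined for the given inputs (zero range, empty set)."""
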