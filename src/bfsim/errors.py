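"""Exception hierarchy shared across the package."""


class BfsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BfsimError):
    """Invalid or inconsistent configuration values."""


class SizingError(BfsimError):
    """Array too small to contain the structure it must represent."""


class StackFormatError(BfsimError):
    """Malformed image stack (page count, shapes, layout)."""


class DegenerateInputError(BfsimError):
    """Input carries no usable signal (e.g. an all-zero stack)."""


class NoBackgroundError(BfsimError):
    """The in-focus window covers every z slice; no background term exists."""


class InvalidOpticsError(BfsimError):
    """Transfer functions are unusable (e.g. in-focus OTF identically zero)."""


class AliasingError(BfsimError):
    """Requested pattern frequency exceeds the sampling limit."""


class PlacementError(BfsimError):
    """Random object placement could not satisfy its constraints."""


class ValidationError(BfsimError):
    """Generic precondition violation on data passed to an operation."""


class ConditioningError(BfsimError):
    """Linear system too ill-conditioned to solve (degenerate phases)."""


class PatternNotFoundError(BfsimError):
    """Illumination-pattern peak not significant; data unusable."""


class MatchingError(BfsimError):
    """Too many unmatched peaks between two point sets."""


class NoPeakError(BfsimError):
    """Profile contains no peak above its background level."""


class UndefinedFRCError(BfsimError):
    """Fourier ring correlation undefined (constant image)."""


class StageError(BfsimError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")
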