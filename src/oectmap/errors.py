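"""Exception hierarchy.

Every error raised by the library derives from :class:`OectmapError`, so
callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class OectmapError(Exception):
    """Base class for all library errors."""


class InvalidParameterError(OectmapError, ValueError):
    """A physical or model parameter violates its constraints."""


class CharacterizationError(OectmapError):
    """A transfer curve cannot be characterized (too few samples, degenerate shape)."""


class DomainError(OectmapError, ValueError):
    """A query point lies outside the domain of a fitted curve."""


class ExtrapolationError(OectmapError):
    """A current lies outside the invertible range of a transfer model.

    Carries the voltage obtained by clipping to the nearest boundary so
    callers may continue with an explicit extrapolation flag.
    """

    def __init__(self, message: str, clipped_voltage: float):
        super().__init__(message)
        self.clipped_voltage = clipped_voltage


class WindowError(OectmapError, ValueError):
    """A requested analysis window does not fit inside the trace."""


class DetectionError(OectmapError):
    """Peak detection failed (empty search span)."""


class DataError(OectmapError, ValueError):
    """Input data violate a method's requirements (e.g. nonpositive values for a log fit)."""


class FitError(OectmapError):
    """A regression or curve fit cannot be performed."""


class ScenarioError(OectmapError, ValueError):
    """A synthetic-experiment configuration is inconsistent."""


class FormatError(OectmapError, ValueError):
    """A file does not conform to the expected on-disk format."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ComparisonError(OectmapError, ValueError):
    """A statistical comparison was requested on insufficient data."""
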