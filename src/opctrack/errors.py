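"""Exception hierarchy for the opctrack pipeline.

Every error raised on purpose by the package derives from
:class:`OpctrackError`, so callers (and the CLI) can distinguish user /
data problems from genuine bugs.
"""


class OpctrackError(Exception):
    """Base class for all errors raised by opctrack."""


class ConfigurationError(OpctrackError):
    """A configuration value violates a precondition or invariant."""


class DegenerateFrameError(OpctrackError):
    """A frame is degenerate for the requested operation (e.g. zero variance)."""

    def __init__(self, frame_index: int, message: str):
        self.frame_index = frame_index
        super().__init__(f"frame {frame_index}: {message}")


class RegistrationError(OpctrackError):
    """Translation estimation is undefined for the given frames."""


class UnsupportedFormatError(OpctrackError):
    """Input file is not a single-channel multi-page image."""


class ParseError(OpctrackError):
    """A file could not be parsed (truncated or malformed)."""


class UndefinedStatisticError(OpctrackError):
    """A trajectory statistic is undefined (too few points, zero duration)."""


class InsufficientDataError(OpctrackError):
    """Not enough observations to fit a model."""


class OutOfCordError(OpctrackError):
    """A scored position lies outside the annotated spinal-cord boundaries."""


class ContractViolation(OpctrackError):
    """An internal contract between pipeline stages was violated."""
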