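"""Exception types shared across the package."""


class RhythmflowError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RhythmflowError, ValueError):
    """Invalid simulation or run configuration."""


class FormatError(RhythmflowError, ValueError):
    """Unreadable or malformed input file."""


class ChannelError(RhythmflowError, ValueError):
    """Requested audio channel does not exist."""


class LengthError(RhythmflowError, ValueError):
    """A series is too short (or too long) for the requested operation."""


class AlignmentError(RhythmflowError, ValueError):
    """Component series of a joint construction have mismatched lengths."""


class PairingError(RhythmflowError, ValueError):
    """Participant records cannot be matched into pairs."""


class StateError(RhythmflowError, RuntimeError):
    """Operation called on an object in an invalid state (e.g. empty null)."""


class FitError(RhythmflowError, RuntimeError):
    """A regression model could not be fitted (singular design, separation)."""
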