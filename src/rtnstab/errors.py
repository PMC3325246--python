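"""Exception hierarchy for rtnstab."""


class RTNError(Exception):
    """Base class for all package errors."""


class ParameterError(RTNError, ValueError):
    """An ensemble or dynamics parameter is out of its legal range."""


class GuardError(RTNError):
    """An exact-enumeration request exceeds the configured size bound.

    Carries the computed size so callers can report how large the refused
    space actually is.
    """

    def __init__(self, message: str, size: int):
        super().__init__(f"{message} (size {size})")
        self.size = size


class GenerationError(RTNError):
    """Random-network generation failed after bounded retries."""


class FitError(RTNError):
    """A distribution fit has insufficient support."""


class ConfigError(RTNError, ValueError):
    """An experiment configuration fails schema validation."""
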