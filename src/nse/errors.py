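"""Exception hierarchy for the nse package."""


class NseError(Exception):
    """Base class for all nse-specific errors."""


class DegenerateSignalError(NseError):
    """Raised when a signal cannot be normalized (zero variance / too short)."""

    def __init__(self, message: str, channel=None):
        self.channel = channel
        if channel is not None:
            message = f"channel {channel!r}: {message}"
        super().__init__(message)


class BandTooNarrowError(NseError):
    """Raised when a frequency band contains no integer candidate period."""


class WindowTooShortError(NseError):
    """Raised when the analysis window is shorter than the requested period."""


class DegenerateSpectrumError(NseError):
    """Raised when spectral parameters are requested from a flat spectrum."""


class StreamCorruptError(NseError):
    """Raised when a non-finite sample reaches the streaming estimator.

    Carries the global sample counter ``k`` at which corruption occurred.
    """

    def __init__(self, message: str, k: int):
        self.k = k
        super().__init__(f"{message} (at sample k={k})")


class RaggedInputError(NseError):
    """Raised for multichannel inputs whose channels differ in length."""


class SignalParseError(NseError):
    """Raised when a delimited text file contains a non-numeric token.

    Carries the 1-based ``line`` number of the offending row.
    """

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"{message} (line {line})")


class RadixError(NseError):
    """Raised when a DFT window length is not a power of two."""


class ValidationError(NseError):
    """Raised for invalid configuration or generator specifications."""
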