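"""Exception types shared across the package."""


class BlowspiroError(Exception):
    """Base class for package errors."""


class AudioFormatError(BlowspiroError):
    """Input file is not a readable PCM WAV."""


class DegenerateInputError(BlowspiroError):
    """Input is valid in type but degenerate in content (e.g. all-zero signal)."""
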