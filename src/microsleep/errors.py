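"""Exception hierarchy shared across the package."""


class MicrosleepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MicrosleepError):
    """A file could not be parsed in the expected format."""


class ChannelError(MicrosleepError, KeyError):
    """A requested channel or derivation could not be resolved."""


class RateMismatchError(MicrosleepError):
    """Sampling rates disagree between channels or with the expected rate."""


class IntervalError(MicrosleepError, ValueError):
    """An event interval is malformed (end <= start, negative start, ...)."""


class EventOverlapError(MicrosleepError, ValueError):
    """Two scored events overlap; scorings must tile the recording."""


class DataError(MicrosleepError, ValueError):
    """Input data violate a precondition (non-finite, wrong length, ...)."""


class SizeError(MicrosleepError, ValueError):
    """An input is too short/long for the requested operation."""


class ConfigurationError(MicrosleepError, ValueError):
    """A model or simulation configuration is unsupported."""


class TrainingError(MicrosleepError, RuntimeError):
    """Training diverged (non-finite loss) or could not proceed."""
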