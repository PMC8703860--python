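"""Exception types shared across the package."""


class StressFSError(Exception):
    """Base class for all package-specific errors."""


class InvalidBandError(StressFSError, ValueError):
    """A frequency band lies outside the representable range (e.g. above Nyquist)."""


class TooShortSignalError(StressFSError, ValueError):
    """A signal is too short for the requested operation (filtering, moments, ...)."""


class InsufficientChannelsError(StressFSError, ValueError):
    """An operation needs more channels than the recording provides."""


class ScheduleError(StressFSError, ValueError):
    """An epoch schedule entry is empty or falls outside the recording."""


class ConstantSignalError(StressFSError, ValueError):
    """A feature is undefined on a (locally) constant signal."""


class ExtractionError(StressFSError, RuntimeError):
    """Feature extraction failed for every epoch, or for an entire column."""


class ConstantColumnError(StressFSError, ValueError):
    """A feature column has zero spread and cannot be standardized."""


class DegenerateLabelsError(StressFSError, ValueError):
    """Labels contain fewer than two classes where two are required."""


class ConfigError(StressFSError, ValueError):
    """A configuration object violates one or more of its invariants."""


class InsufficientDataError(StressFSError, ValueError):
    """Not enough rows per class for the requested split or fit."""


class LeakageError(StressFSError, RuntimeError):
    """Internal consistency guard: train and test partitions overlap."""
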