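"""Exception hierarchy for the pipeline."""


class CommonDriveError(Exception):
    """Base class for all package errors."""


class ValidationError(CommonDriveError, ValueError):
    """An input violates a documented precondition or invariant."""


class ConfigurationError(CommonDriveError, ValueError):
    """Required configuration (e.g. sampling rate metadata) is missing or invalid."""


class InsufficientDataError(CommonDriveError, ValueError):
    """Not enough data for the requested estimator (e.g. fewer than 2 segments)."""


class DegenerateSignalError(CommonDriveError, ValueError):
    """A signal is degenerate for the requested operation (e.g. constant input)."""
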