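"""Exception hierarchy.

Two broad families mirror the CLI exit codes: :class:`ValidationError`
(bad parameters / configuration, exit code 2) and :class:`DataError`
(structurally valid call on data that cannot be processed, exit code 3).
"""


class SynergaitError(Exception):
    """Base class for all package errors."""


class ValidationError(SynergaitError, ValueError):
    """Invalid parameter or configuration value."""


class DataError(SynergaitError, ValueError):
    """Input data violates a processing precondition."""


class InvalidParameterError(ValidationError):
    """A numeric parameter is out of its valid range (e.g. cutoff >= Nyquist)."""


class TooShortError(DataError):
    """Signal or stride too short for the requested operation."""


class InsufficientEventsError(DataError):
    """Fewer gait events than the operation requires."""


class OutOfRangeEventError(DataError):
    """A gait event falls outside the recording span."""


class DegenerateChannelError(DataError):
    """An EMG channel is flat (no usable amplitude) where activity is required."""


class InsufficientStridesError(DataError):
    """Not enough strides remain after trimming to select the requested count."""


class DegenerateInputError(DataError):
    """Matrix input is degenerate for factorization (all zero, negative entries...)."""


class DegenerateSynergyError(DataError):
    """A synergy weight column has zero norm."""


class SequenceViolationError(DataError):
    """Gait events do not follow the expected 6-phase cyclic order."""


class ConfigError(ValidationError):
    """Configuration file contains unknown or invalid keys."""
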