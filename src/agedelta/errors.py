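"""Exception hierarchy for agedelta.

All package-specific failures derive from :class:`AgeDeltaError` so callers
can catch one base class; each subclass marks a distinct failure mode of the
estimation / adjustment pipeline.
"""


class AgeDeltaError(Exception):
    """Base class for all agedelta errors."""


class ConfigurationError(AgeDeltaError, ValueError):
    """A configuration object violates its invariants; names the field."""


class DegenerateDataError(AgeDeltaError, ValueError):
    """Input data cannot support the requested fit (too few subjects,
    constant age column, singular design)."""


class InsufficientDataError(AgeDeltaError, ValueError):
    """A statistical procedure received fewer observations than it needs."""


class SchemeMismatchError(AgeDeltaError, ValueError):
    """An offset model of one scheme was passed to the other scheme's
    application function."""


class UnstableAdjustmentError(AgeDeltaError, ValueError):
    """Rescaling adjustment refused: the fitted slope is too close to zero,
    so dividing by it would inflate variance without bound."""


class PairingError(AgeDeltaError, ValueError):
    """Paired vectors (same subjects under two methods) have unequal
    lengths."""


class ShapeError(AgeDeltaError, ValueError):
    """Feature-vector length does not match what a fitted model expects."""
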