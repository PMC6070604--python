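"""Exception hierarchy for clonedist.

All package-specific failures derive from :class:`ClonedistError` so callers
(and the CLI) can distinguish data/model problems from programming errors.
"""


class ClonedistError(Exception):
    """Base class for all clonedist errors."""


class FormatError(ClonedistError):
    """Input table does not conform to the expected AIRR/Change-O dialect."""


class ConsistencyError(ClonedistError):
    """Internal invariant violated (e.g. unassigned sequence, length mismatch)."""


class InsufficientDataError(ClonedistError):
    """Too few distance values to fit the mixture model."""


class DegenerateDataError(ClonedistError):
    """Distance vector has no variation; a two-component fit is meaningless."""


class DegenerateModelError(ClonedistError):
    """Fitted model places no usable mass inside the threshold interval."""


class NumericalError(ClonedistError):
    """Non-finite likelihood or other numerical failure during fitting."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class ConfigError(ClonedistError):
    """Invalid simulation configuration; message lists all violations."""
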