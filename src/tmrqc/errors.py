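"""Exception hierarchy shared across the package.

All domain errors derive from :class:`TMRQCError` so callers (and the CLI)
can separate validation failures from genuine computation failures.
"""


class TMRQCError(Exception):
    """Base class for all tmrqc errors."""


class ParameterError(TMRQCError, ValueError):
    """An argument or configuration value is invalid (non-finite, out of range)."""


class InputValidationError(TMRQCError, ValueError):
    """An input table or vector fails schema or range checks.

    ``report`` carries an itemised list of problems when available.
    """

    def __init__(self, message: str, report: list[str] | None = None):
        super().__init__(message)
        self.report = list(report or [])


class DegenerateInputError(TMRQCError, ValueError):
    """Input is formally valid but degenerate for the requested operation
    (constant spectrum, all-zero sieve fractions, < 3 surviving points...)."""


class DataIntegrityError(TMRQCError, ValueError):
    """Records that must agree do not (e.g. conflicting categorical values
    across repeated visits to the same farm)."""


class NotComputableError(TMRQCError):
    """The quantity cannot be computed from the data provided (e.g. the
    sorting index without the +2 h resampling) — distinct from a zero value."""
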