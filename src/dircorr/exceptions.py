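"""Exception hierarchy for dircorr.

All estimator-level failures derive from :class:`DircorrError` so callers
(and the CLI) can catch one base class.  Degenerate data (a constant
variable, zero total sum of squares) is deliberately an *error*, never a
silent zero: returning 0 for a constant item would be indistinguishable
from a genuine null association.
"""


class DircorrError(Exception):
    """Base class for all dircorr errors."""


class InvalidInputError(DircorrError, ValueError):
    """Input violates a precondition (wrong scale, bad range, bad label)."""


class DegenerateInputError(DircorrError, ValueError):
    """A variable is constant / has zero variance where variance is required."""


class UndefinedStatisticError(DircorrError, ValueError):
    """The statistic's denominator is zero (e.g. all pairs tied)."""


class CollinearPredictorsError(InvalidInputError):
    """Two predictors correlate perfectly; the multiple-R formula is singular."""
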