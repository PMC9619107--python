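"""Core value types shared across the estimator modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import InvalidInputError

#: Direction labels for association estimates.  ``g_given_X`` groups the
#: wide-scale variable X by the categories of the narrow-scale variable g
#: (the item-analysis reading "the score explains the item"); ``X_given_g``
#: is the mirror direction; symmetric estimators use ``symmetric`` and the
#: product-moment correlation itself ``not_applicable``.
G_GIVEN_X = "g_given_X"
X_GIVEN_G = "X_given_g"
SYMMETRIC = "symmetric"
NOT_APPLICABLE = "not_applicable"

DIRECTIONS = (G_GIVEN_X, X_GIVEN_G)


@dataclass(frozen=True)
class PairedSeries:
    """Two paired observation vectors: an ordinal item g and a metric score X.

    Parameters
    ----------
    g
        Ordinal categories coded as non-negative integers.  Few categories
        expected (binary items are the extreme case).
    x
        Metric values (ordinal, interval or continuous scale).

    The pair is the unit of every bivariate estimator in this package.
    Construction validates equal length, absence of missing values and the
    integer coding of g.
    """

    g: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g)
        x = np.asarray(self.x, dtype=float)
        if g.ndim != 1 or x.ndim != 1:
            raise InvalidInputError("g and x must be one-dimensional vectors")
        if len(g) != len(x):
            raise InvalidInputError(
                f"length mismatch: len(g)={len(g)} != len(x)={len(x)}"
            )
        if len(g) < 2:
            raise InvalidInputError("at least two paired observations required")
        if np.any(~np.isfinite(x)):
            raise InvalidInputError("x contains missing or non-finite values")
        gf = np.asarray(g, dtype=float)
        if np.any(~np.isfinite(gf)):
            raise InvalidInputError("g contains missing or non-finite values")
        if np.any(gf != np.round(gf)) or np.any(gf < 0):
            raise InvalidInputError("g must contain non-negative integers")
        object.__setattr__(self, "g", gf.astype(np.int64))
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        """Number of paired observations."""
        return len(self.g)

    @property
    def n_categories_g(self) -> int:
        """Observed number of distinct categories in g (R)."""
        return len(np.unique(self.g))

    @property
    def n_categories_x(self) -> int:
        """Observed number of distinct values in X (C)."""
        return len(np.unique(self.x))

    @property
    def difficulty(self) -> float:
        """Item difficulty p = mean(g)/max(g); proportion correct for binary g."""
        gmax = self.g.max()
        if gmax == 0:
            raise InvalidInputError("difficulty undefined: g is constant at 0")
        return float(self.g.mean() / gmax)

    @property
    def is_binary(self) -> bool:
        return set(np.unique(self.g)) <= {0, 1} and self.n_categories_g == 2


@dataclass(frozen=True)
class AssociationEstimate:
    """A single association estimate with its name and direction label."""

    value: float
    estimator_name: str
    direction: str = NOT_APPLICABLE

    def __post_init__(self) -> None:
        if abs(self.value) > 1 + 1e-9:
            raise InvalidInputError(
                f"{self.estimator_name} produced |value| > 1: {self.value!r}"
            )

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class GroupDecomposition:
    """Between/within/total sum-of-squares decomposition of one variable
    grouped by the categories of the other (the one-way ANOVA identity)."""

    ss_between: float
    ss_within: float
    ss_total: float
    group_means: Mapping[float, float] = field(default_factory=dict)
    grand_mean: float = float("nan")

    def __post_init__(self) -> None:
        if self.ss_between < -1e-12 or self.ss_within < -1e-12:
            raise InvalidInputError("sums of squares must be non-negative")
        resid = abs(self.ss_between + self.ss_within - self.ss_total)
        if resid > 1e-9 * max(1.0, abs(self.ss_total)):
            raise InvalidInputError(
                "ss_between + ss_within != ss_total "
                f"({self.ss_between} + {self.ss_within} != {self.ss_total})"
            )
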