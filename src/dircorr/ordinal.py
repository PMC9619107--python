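"""Concordance-based ordinal association measures.

Every statistic here is a function of the classification of all n(n-1)/2
unordered observation pairs into five classes: concordant, discordant,
tied on g only, tied on X only, tied on both.  Goodman-Kruskal gamma
discards all ties; the Somers deltas restrict the denominator to the pairs
that differ on a designated variable; Kendall tau-b is the geometric-mean
compromise.  The direction naming follows the convention of this package's
worked dataset: "g given X" divides by the pairs that *differ on g*.

Counting is done on the R x C contingency table with two-dimensional
cumulative sums, so the cost is O(n log n + R·C) rather than O(n²); the
test suite checks it pair-for-pair against a brute-force enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .estimators import _corr
from .exceptions import DegenerateInputError, InvalidInputError, UndefinedStatisticError
from .types import (
    G_GIVEN_X,
    NOT_APPLICABLE,
    SYMMETRIC,
    X_GIVEN_G,
    AssociationEstimate,
    PairedSeries,
)

__all__ = [
    "PairCounts",
    "pair_counts",
    "gamma",
    "somers_d",
    "kendall_tau_b",
    "spearman_rho",
    "item_rest_correlation",
]


@dataclass(frozen=True)
class PairCounts:
    """Exhaustive classification of all unordered observation pairs."""

    concordant: int
    discordant: int
    tied_g_only: int
    tied_x_only: int
    tied_both: int

    @property
    def total_pairs(self) -> int:
        return (
            self.concordant
            + self.discordant
            + self.tied_g_only
            + self.tied_x_only
            + self.tied_both
        )

    @property
    def net(self) -> int:
        """C − D, the numerator shared by gamma, the deltas and tau-b."""
        return self.concordant - self.discordant


def pair_counts(pair: PairedSeries) -> PairCounts:
    """Classify every unordered pair of observations.

    Uses the contingency table of (g, X): with T the R x C count matrix,
    the concordant total is sum_ij T_ij * (count strictly below-right) and
    the tie classes come from the marginal tie counts.
    """
    g_codes = np.unique(pair.g, return_inverse=True)[1]
    x_codes = np.unique(pair.x, return_inverse=True)[1]
    n = pair.n
    table = np.zeros((g_codes.max() + 1, x_codes.max() + 1), dtype=np.int64)
    np.add.at(table, (g_codes, x_codes), 1)

    def _pairs(v: np.ndarray) -> int:
        return int(np.sum(v * (v - 1) // 2))

    tied_both = _pairs(table.ravel())
    tied_g = _pairs(table.sum(axis=1)) - tied_both
    tied_x = _pairs(table.sum(axis=0)) - tied_both

    # strictly-below-right cumulative: S[i, j] = sum_{k>i, l>j} T[k, l]
    below_right = np.zeros_like(table)
    below_right[:-1, :-1] = table[1:, 1:][::-1, ::-1].cumsum(0).cumsum(1)[::-1, ::-1]
    concordant = int(np.sum(table * below_right))

    total = n * (n - 1) // 2
    discordant = total - concordant - tied_both - tied_g - tied_x
    return PairCounts(concordant, discordant, tied_g, tied_x, tied_both)


def gamma(pair: PairedSeries) -> AssociationEstimate:
    """Goodman-Kruskal gamma: (C − D)/(C + D) over the untied pairs.

    Insensitive to ties, which is exactly why it can detect a deterministic
    item-score pattern that the product-moment correlation cannot.
    """
    c = pair_counts(pair)
    denom = c.concordant + c.discordant
    if denom == 0:
        raise UndefinedStatisticError("all pairs tied: gamma undefined")
    return AssociationEstimate(c.net / denom, "gamma", SYMMETRIC)


def somers_d(pair: PairedSeries, direction: str) -> AssociationEstimate:
    """Somers delta: (C − D) over the pairs differing on the designated variable.

    ``g_given_X`` divides by the pairs whose g values differ
    (C + D + tied-on-X-only); ``X_given_g`` divides by the pairs whose X
    values differ; ``symmetric`` uses the average of the two denominators.
    """
    c = pair_counts(pair)
    d_g = c.concordant + c.discordant + c.tied_x_only  # pairs differing on g
    d_x = c.concordant + c.discordant + c.tied_g_only  # pairs differing on X
    if direction == G_GIVEN_X:
        denom = d_g
    elif direction == X_GIVEN_G:
        denom = d_x
    elif direction == SYMMETRIC:
        denom = (d_g + d_x) / 2.0
    else:
        raise InvalidInputError(f"unknown somers_d direction {direction!r}")
    if denom == 0:
        raise UndefinedStatisticError("zero denominator: Somers delta undefined")
    return AssociationEstimate(c.net / denom, "somers_d", direction)


def kendall_tau_b(pair: PairedSeries) -> AssociationEstimate:
    """Kendall tau-b: (C − D)/sqrt((pairs differing on g)(pairs differing on X)).

    The signed geometric mean of the two directional Somers deltas.
    """
    c = pair_counts(pair)
    d_g = c.concordant + c.discordant + c.tied_x_only
    d_x = c.concordant + c.discordant + c.tied_g_only
    if d_g == 0 or d_x == 0:
        raise UndefinedStatisticError("zero denominator: tau-b undefined")
    return AssociationEstimate(c.net / math.sqrt(d_g * d_x), "kendall_tau_b", SYMMETRIC)


def spearman_rho(pair: PairedSeries) -> AssociationEstimate:
    """Spearman rank correlation: product-moment correlation of mid-ranks."""
    rg = rankdata(pair.g, method="average")
    rx = rankdata(pair.x, method="average")
    try:
        value = _corr(rg, rx)
    except DegenerateInputError as exc:
        raise DegenerateInputError("constant ranks: Spearman rho undefined") from exc
    return AssociationEstimate(value, "spearman_rho", SYMMETRIC)


def item_rest_correlation(pair: PairedSeries) -> AssociationEstimate:
    """Item-rest correlation: PMC between the item g and the rest score X − g.

    Assumes X is a sum score that contains g; removing the item avoids the
    mechanical part-whole inflation of the plain item-score correlation.
    """
    rest = pair.x - pair.g
    if np.ptp(rest) == 0:
        raise DegenerateInputError("rest score X - g is constant")
    value = _corr(pair.g, rest)
    return AssociationEstimate(value, "item_rest_correlation", NOT_APPLICABLE)
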