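"""Product-moment correlation, coefficient eta, and related closed forms.

The central fact exploited throughout this package is that the
product-moment correlation (PMC) between a narrow-scale ordinal variable g
and a wide-scale metric variable X is not a symmetric measure: for binary g
it coincides exactly with coefficient eta directed "g given X" (the score
explains the response pattern in the item), and for polytomous ordinal g it
is bounded above by that same eta.  All moments here are population
(divide-by-n) moments; the correlation is invariant to the choice, and the
point-biserial closed form sigma_g = sqrt(p(1-p)) requires it.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import (
    CollinearPredictorsError,
    DegenerateInputError,
    InvalidInputError,
)
from .types import (
    DIRECTIONS,
    G_GIVEN_X,
    NOT_APPLICABLE,
    X_GIVEN_G,
    AssociationEstimate,
    GroupDecomposition,
    PairedSeries,
)

__all__ = [
    "pmc",
    "point_biserial",
    "eta",
    "eta_signed",
    "eta_squared",
    "ss_decomposition",
    "multiple_r_two_predictors",
]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa = a.std()  # population SD
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        raise DegenerateInputError("zero variance: correlation undefined")
    cov = float(np.mean((a - a.mean()) * (b - b.mean())))
    return min(1.0, max(-1.0, cov / (sa * sb)))


def pmc(pair: PairedSeries) -> AssociationEstimate:
    """Product-moment correlation between g and X.

    value = sigma_gX / (sigma_g * sigma_X) with population moments.
    Symmetric in its two arguments; the *interpretation* is directional
    whenever the scales differ, which is what the rest of the package
    quantifies.

    Raises
    ------
    DegenerateInputError
        If either variable is constant.
    """
    return AssociationEstimate(_corr(pair.g, pair.x), "pmc", NOT_APPLICABLE)


def point_biserial(pair: PairedSeries) -> AssociationEstimate:
    """Point-biserial correlation (X̄₁ − X̄₀)·σ_g/σ_X for binary g.

    Algebraically identical to :func:`pmc` when g ∈ {0, 1}; kept separate
    because the closed form makes the sign rule (the order of the group
    means) explicit.
    """
    if not pair.is_binary:
        raise InvalidInputError("point_biserial requires g with values {0, 1}")
    x = pair.x
    mask = pair.g == 1
    p = mask.mean()
    sigma_g = math.sqrt(p * (1.0 - p))
    sigma_x = x.std()
    if sigma_x == 0.0:
        raise DegenerateInputError("X is constant: point-biserial undefined")
    value = (x[mask].mean() - x[~mask].mean()) * sigma_g / sigma_x
    return AssociationEstimate(
        min(1.0, max(-1.0, float(value))), "point_biserial", NOT_APPLICABLE
    )


def ss_decomposition(pair: PairedSeries, direction: str) -> GroupDecomposition:
    """Between/within/total sums of squares of one variable grouped by the other.

    ``g_given_X`` decomposes the values of X over the categories of g;
    ``X_given_g`` decomposes the values of g over the distinct values of X.
    The additivity ss_between + ss_within = ss_total is enforced by the
    returned :class:`GroupDecomposition`.
    """
    if direction == G_GIVEN_X:
        dep, grp = pair.x.astype(float), pair.g
    elif direction == X_GIVEN_G:
        dep, grp = pair.g.astype(float), pair.x
    else:
        raise InvalidInputError(
            f"direction must be one of {DIRECTIONS}, got {direction!r}"
        )
    grand = dep.mean()
    ss_total = float(np.sum((dep - grand) ** 2))
    levels, inverse, counts = np.unique(grp, return_inverse=True, return_counts=True)
    sums = np.bincount(inverse, weights=dep)
    means = sums / counts
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_between = min(ss_between, ss_total)  # guard fp overshoot
    return GroupDecomposition(
        ss_between=ss_between,
        ss_within=ss_total - ss_between,
        ss_total=ss_total,
        group_means={float(k): float(v) for k, v in zip(levels, means)},
        grand_mean=float(grand),
    )


def eta(pair: PairedSeries, direction: str) -> AssociationEstimate:
    """Coefficient eta (correlation ratio) sqrt(SS_between/SS_total).

    Inherently directional: eta(g_given_X) groups X by the item categories
    and is the direction that equals |PMC| for binary g; eta(X_given_g)
    groups the item by the score values and reaches 1 exactly when no score
    value maps to two different item categories.
    """
    dec = ss_decomposition(pair, direction)
    if dec.ss_total == 0.0:
        raise DegenerateInputError("grouped variable is constant: eta undefined")
    return AssociationEstimate(
        math.sqrt(dec.ss_between / dec.ss_total), "eta", direction
    )


def eta_squared(pair: PairedSeries, direction: str) -> float:
    """Explained-variance ratio SS_between/SS_total (eta² exactly)."""
    dec = ss_decomposition(pair, direction)
    if dec.ss_total == 0.0:
        raise DegenerateInputError("grouped variable is constant: eta² undefined")
    return dec.ss_between / dec.ss_total


def eta_signed(pair: PairedSeries) -> AssociationEstimate:
    """Eta in the g-given-X direction with the sign of the association.

    The conventional eta formula squares everything and so reports only the
    magnitude.  For binary g the factual sign is sign(X̄₁ − X̄₀); for
    polytomous ordinal g this package takes the sign of the product-moment
    correlation.  Requires ordinal g — for nominal grouping a signed value
    has no meaning.
    """
    magnitude = eta(pair, G_GIVEN_X).value
    if pair.is_binary:
        x1 = pair.x[pair.g == 1].mean()
        x0 = pair.x[pair.g == 0].mean()
        sign = 1.0 if x1 >= x0 else -1.0
    else:
        sign = 1.0 if pmc(pair).value >= 0 else -1.0
    return AssociationEstimate(sign * magnitude, "eta_signed", G_GIVEN_X)


def multiple_r_two_predictors(r_yx: float, r_yz: float, r_xz: float) -> float:
    """Multiple correlation R of y on two predictors from the three pairwise
    correlations:

        R = sqrt((r_yx² + r_yz² − 2 r_yx r_yz r_xz) / (1 − r_xz²))

    Raises
    ------
    CollinearPredictorsError
        If |r_xz| = 1.
    InvalidInputError
        If any input is outside [−1, 1] or the triple is not a valid
        (positive semi-definite) correlation matrix.
    """
    for name, r in (("r_yx", r_yx), ("r_yz", r_yz), ("r_xz", r_xz)):
        if not -1.0 <= r <= 1.0:
            raise InvalidInputError(f"{name}={r} outside [-1, 1]")
    if abs(r_xz) == 1.0:
        raise CollinearPredictorsError("predictors correlate perfectly")
    radicand = (r_yx**2 + r_yz**2 - 2.0 * r_yx * r_yz * r_xz) / (1.0 - r_xz**2)
    if radicand < -1e-12 or radicand > 1.0 + 1e-9:
        raise InvalidInputError(
            "correlation triple is not positive semi-definite "
            f"(R² would be {radicand:.6f})"
        )
    return math.sqrt(min(1.0, max(0.0, radicand)))
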