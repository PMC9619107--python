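"""Attenuation-corrected correlation and eta.

With the observed margins of g and X fixed, the two variances are fixed,
so the only free element of the product-moment correlation is the
covariance.  By the rearrangement inequality the covariance is maximal
when both variables are sorted into the same (ascending) order; the
correlation of the independently sorted copies is therefore the maximal
correlation attainable in the given dataset.  Dividing the observed
estimate by that ceiling gives the attenuation-corrected correlation R_AC
and, with eta in the g-given-X direction, the attenuation-corrected eta
E_AC (E_AC² for explained variance).  The gap between observed and maximal
is mechanical deflation — an artefact of scale discrepancy, difficulty and
ties — not sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .estimators import eta, pmc
from .exceptions import UndefinedStatisticError
from .ordinal import gamma, kendall_tau_b, somers_d
from .types import (
    G_GIVEN_X,
    SYMMETRIC,
    X_GIVEN_G,
    AssociationEstimate,
    PairedSeries,
)

__all__ = ["DeflationReport", "max_pmc", "max_eta", "r_ac", "e_ac", "deflation_report"]


def _sorted_pair(pair: PairedSeries, order: str = "concordant") -> PairedSeries:
    g = np.sort(pair.g)
    x = np.sort(pair.x)
    if order == "discordant":
        g = g[::-1]
    elif order != "concordant":
        raise ValueError(f"order must be 'concordant' or 'discordant', not {order!r}")
    return PairedSeries(g, x)


def max_pmc(pair: PairedSeries, order: str = "concordant") -> float:
    """Maximal product-moment correlation for the observed margins.

    Computed between independently ascending-sorted copies of g and X.
    ``order='discordant'`` instead reverses g and yields the minimal (most
    negative) attainable correlation.  The value is invariant to how tied
    observations are permuted: the sorted cross-moment is unique.
    """
    return pmc(_sorted_pair(pair, order)).value


def max_eta(pair: PairedSeries, order: str = "concordant") -> float:
    """Eta (g given X) between independently sorted copies of g and X.

    For binary g this equals :func:`max_pmc` by the binary PMC-eta
    equivalence.  For polytomous g it is taken as the definition of the
    maximal eta under the observed margins.
    """
    return eta(_sorted_pair(pair, order), G_GIVEN_X).value


def r_ac(pair: PairedSeries) -> AssociationEstimate:
    """Attenuation-corrected correlation: observed PMC over maximal PMC.

    The correction is applied to the magnitude and the observed sign is
    reattached, so a negative association corrects toward −1.
    """
    ceiling = max_pmc(pair)
    if ceiling <= 0.0:
        raise UndefinedStatisticError("maximal correlation is zero: R_AC undefined")
    observed = pmc(pair).value
    value = abs(observed) / ceiling
    value = min(1.0, value)  # fp guard; |observed| <= ceiling by rearrangement
    return AssociationEstimate(float(np.sign(observed)) * value, "r_ac", G_GIVEN_X)


def e_ac(pair: PairedSeries) -> AssociationEstimate:
    """Attenuation-corrected eta: observed eta (g given X) over maximal eta."""
    ceiling = max_eta(pair)
    if ceiling <= 0.0:
        raise UndefinedStatisticError("maximal eta is zero: E_AC undefined")
    value = min(1.0, eta(pair, G_GIVEN_X).value / ceiling)
    return AssociationEstimate(value, "e_ac", G_GIVEN_X)


@dataclass(frozen=True)
class DeflationReport:
    """Observed estimators, their attenuation-corrected counterparts, and
    the relative deflation of the product-moment correlation."""

    observed: Mapping[str, float]
    corrected: Mapping[str, float]
    deflation_percent: float

    def as_rows(self) -> list[tuple[str, str, float]]:
        rows = [("observed", k, v) for k, v in self.observed.items()]
        rows += [("corrected", k, v) for k, v in self.corrected.items()]
        rows.append(("summary", "deflation_percent", self.deflation_percent))
        return rows


def deflation_report(pair: PairedSeries) -> DeflationReport:
    """Tabulate observed and corrected estimators for one item-score pair.

    deflation_percent = (R_AC − |PMC|)/R_AC on magnitudes: the fraction of
    the attainable correlation that the observed estimate loses to
    mechanical deflation.
    """
    observed = {
        "pmc": pmc(pair).value,
        "eta_g_given_X": eta(pair, G_GIVEN_X).value,
        "eta_X_given_g": eta(pair, X_GIVEN_G).value,
        "gamma": gamma(pair).value,
        "somers_d_g_given_X": somers_d(pair, G_GIVEN_X).value,
        "somers_d_X_given_g": somers_d(pair, X_GIVEN_G).value,
        "somers_d_symmetric": somers_d(pair, SYMMETRIC).value,
        "kendall_tau_b": kendall_tau_b(pair).value,
    }
    corrected = {
        "max_pmc": max_pmc(pair),
        "max_eta": max_eta(pair),
        "r_ac": r_ac(pair).value,
        "e_ac": e_ac(pair).value,
        "e_ac_squared": e_ac(pair).value ** 2,
    }
    deflation = (abs(corrected["r_ac"]) - abs(observed["pmc"])) / abs(corrected["r_ac"])
    return DeflationReport(observed, corrected, deflation)
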