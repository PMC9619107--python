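"""Item-level directionality analysis and effect-size summaries.

Given a persons x items response matrix, each item g is paired with the
sum score X and the full battery of estimators is computed per item.  The
quantity of interest is the discrepancy between the two directions of eta
(eta2 − eta1): it measures how far the item-score association is from a
symmetric one, and it is driven by the scale discrepancy between item and
score, indexed by the C/R ratio (score categories over item categories).
The module summarizes that discrepancy over bins of the item's degrees of
freedom or of C/R, and provides the standard one-way effect-size machinery
(F, eta², Cohen's f and d, Sidak-adjusted pairwise comparisons) used to
judge whether the directionality is practically remarkable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .attenuation import e_ac, max_eta, max_pmc, r_ac
from .estimators import eta, pmc
from .exceptions import DircorrError, InvalidInputError
from .types import G_GIVEN_X, X_GIVEN_G, PairedSeries

__all__ = [
    "EffectSummary",
    "item_analysis_table",
    "binned_difference_summary",
    "oneway_effect_sizes",
    "cohen_d",
    "sidak_pairwise",
    "TABLE_CR_BIN_EDGES",
]

#: Preset C/R bin edges for the scale-discrepancy summary (bins are
#: left-open intervals (a, b]; the first bin is <= the first edge).
TABLE_CR_BIN_EDGES: tuple[float, ...] = (
    1.929, 2.5, 3.111, 3.909, 4.333, 5.0, 6.833, 9.333, 10.5, 12.5, 14.0,
)

_ITEM_COLUMNS = [
    "item", "n", "p", "variance", "df_g", "df_X", "cr_ratio",
    "rit", "eta1", "eta2", "diff", "r_ac", "e_ac", "max_pmc", "max_eta", "flag",
]


def item_analysis_table(
    matrix: pd.DataFrame, score: pd.Series | None = None
) -> pd.DataFrame:
    """Per-item estimator table for a persons x items response matrix.

    Parameters
    ----------
    matrix
        Response matrix, one column per item, non-negative integer cells.
    score
        Total score; defaults to the row sum of ``matrix``.

    Returns a DataFrame with one row per item: difficulty ``p``, item
    variance, observed degrees of freedom ``df_g``/``df_X`` (distinct
    categories minus one), scale-discrepancy ratio ``cr_ratio`` =
    (df_X+1)/(df_g+1), the item-score correlation ``rit``, both eta
    directions (``eta1`` = g given X, ``eta2`` = X given g), their
    difference ``diff`` = eta2 − eta1, and the attenuation-corrected
    values.  Degenerate items are kept but flagged, with estimators NaN.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise InvalidInputError("need at least 2 items and 2 persons")
    x = (matrix.sum(axis=1) if score is None else score).to_numpy(dtype=float)
    rows = []
    for name, col in matrix.items():
        g = col.to_numpy()
        rec: dict = {"item": name, "n": len(g), "flag": ""}
        df_g = len(np.unique(g)) - 1
        df_x = len(np.unique(x)) - 1
        rec.update(
            p=float(np.mean(g) / np.max(g)) if np.max(g) > 0 else np.nan,
            variance=float(np.var(g)),
            df_g=df_g,
            df_X=df_x,
            cr_ratio=(df_x + 1) / (df_g + 1),
        )
        try:
            pair = PairedSeries(g, x)
            rec.update(
                rit=pmc(pair).value,
                eta1=eta(pair, G_GIVEN_X).value,
                eta2=eta(pair, X_GIVEN_G).value,
                r_ac=r_ac(pair).value,
                e_ac=e_ac(pair).value,
                max_pmc=max_pmc(pair),
                max_eta=max_eta(pair),
            )
            rec["diff"] = rec["eta2"] - rec["eta1"]
            if rec["diff"] < -1e-9:
                rec["flag"] = "eta1_exceeds_eta2"
        except DircorrError as exc:
            rec.update({k: np.nan for k in
                        ("rit", "eta1", "eta2", "diff", "r_ac", "e_ac",
                         "max_pmc", "max_eta")})
            rec["flag"] = f"undefined: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows, columns=_ITEM_COLUMNS)


def binned_difference_summary(
    rows: pd.DataFrame,
    by: str = "cr_ratio",
    bin_edges: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Mean/SD/count of the eta2 − eta1 discrepancy per bin of ``by``.

    ``by`` is a column of the item table (``df_g`` or ``cr_ratio``).  Bins
    are (a, b] intervals over ``bin_edges`` with open outer bins; if
    ``bin_edges`` is None, each distinct value of ``by`` forms its own bin.
    Returns the per-bin summary (with an ``overall`` row) and the Spearman
    rank correlation of bin index vs bin mean — the monotone-trend
    statistic.
    """
    if by not in rows.columns:
        raise InvalidInputError(f"unknown binning column {by!r}")
    data = rows.dropna(subset=["diff"]).copy()
    if bin_edges is not None:
        if len(bin_edges) == 0:
            raise InvalidInputError("bin_edges must be non-empty")
        edges = [-np.inf, *bin_edges, np.inf]
        data["_bin"] = pd.cut(data[by], bins=edges)
    else:
        data["_bin"] = data[by]
    grouped = data.groupby("_bin", observed=True)["diff"]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    summary = summary.rename(columns={"_bin": "bin"})
    summary = summary[summary["n"] > 0].reset_index(drop=True)
    if summary.empty:
        raise InvalidInputError("no non-empty bins")
    if len(summary) > 2:
        trend = float(
            stats.spearmanr(np.arange(len(summary)), summary["mean"]).statistic
        )
    else:
        trend = float("nan")
    overall = pd.DataFrame(
        [{
            "bin": "overall",
            "mean": data["diff"].mean(),
            "sd": data["diff"].std(),
            "n": len(data),
        }]
    )
    return pd.concat([summary, overall], ignore_index=True), trend


@dataclass(frozen=True)
class EffectSummary:
    """One-way ANOVA effect summary: F(df1, df2), eta² and Cohen's f."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    eta_squared: float
    cohen_f: float
    groups: Mapping[object, tuple[float, float, int]]  # mean, sd, n


def cohen_f_from_eta_squared(eta_squared: float) -> float:
    """Cohen's f = sqrt(eta²/(1 − eta²))."""
    if not 0.0 <= eta_squared < 1.0:
        raise InvalidInputError("eta_squared must be in [0, 1)")
    return math.sqrt(eta_squared / (1.0 - eta_squared))


def oneway_effect_sizes(values: np.ndarray, groups: np.ndarray) -> EffectSummary:
    """One-way ANOVA of ``values`` over ``groups`` with effect sizes."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise InvalidInputError("need at least two groups")
    if len(values) - len(levels) < 1:
        raise InvalidInputError("not enough residual degrees of freedom")
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    per_group = {}
    ss_between = 0.0
    for lev in levels:
        v = values[groups == lev]
        per_group[lev] = (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1
                          else float("nan"), len(v))
        ss_between += len(v) * (v.mean() - grand) ** 2
    df1 = len(levels) - 1
    df2 = len(values) - len(levels)
    ss_within = ss_total - ss_between
    f_stat = (ss_between / df1) / (ss_within / df2) if ss_within > 0 else math.inf
    p = float(stats.f.sf(f_stat, df1, df2)) if math.isfinite(f_stat) else 0.0
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return EffectSummary(
        f_statistic=float(f_stat),
        df_between=df1,
        df_within=df2,
        p_value=p,
        eta_squared=float(eta2),
        cohen_f=cohen_f_from_eta_squared(min(eta2, 1 - 1e-15)),
        groups=per_group,
    )


def cohen_d(mean_difference: float, sd: float) -> float:
    """Cohen's d: a mean difference in units of the standard deviation."""
    if sd <= 0:
        raise InvalidInputError("sd must be positive")
    return mean_difference / sd


def sidak_pairwise(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise group-mean comparisons with Sidak-adjusted p-values.

    Uses Welch (unequal-variance) t-tests; the adjusted p for m
    comparisons is 1 − (1 − p_raw)^m, capped at 1, and the per-comparison
    significance threshold is 1 − (1 − alpha)^(1/m).  Pairs involving a
    group with fewer than two observations are kept but flagged undefined.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(np.unique(groups))
    if len(levels) < 2:
        raise InvalidInputError("need at least two groups")
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    threshold = 1.0 - (1.0 - alpha) ** (1.0 / m)
    rows = []
    for a, b in pairs:
        va, vb = values[groups == a], values[groups == b]
        rec: dict = {
            "group_a": a, "group_b": b,
            "mean_a": va.mean(), "mean_b": vb.mean(),
            "mean_diff": va.mean() - vb.mean(),
        }
        if len(va) < 2 or len(vb) < 2:
            rec.update(t=np.nan, p_raw=np.nan, p_adjusted=np.nan,
                       significant=False, flag="undefined: group with n < 2")
        else:
            t, p_raw = stats.ttest_ind(va, vb, equal_var=False)
            p_adj = min(1.0, 1.0 - (1.0 - p_raw) ** m)
            rec.update(t=float(t), p_raw=float(p_raw), p_adjusted=float(p_adj),
                       significant=bool(p_raw < threshold), flag="")
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["n_comparisons"] = m
    out.attrs["per_comparison_threshold"] = threshold
    return out
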