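"""Latent-variable generation and discretization.

The deflation phenomenon studied by this package is purely mechanical, so
it can be demonstrated with a noiseless construction: take one latent
vector, cut it once into a coarse ordinal item g and once into a finer
score X, and compare the observed item-score correlation with the latent
correlation of exactly 1.  The module also generates whole collections of
simulated tests (persons x items response matrices with sum scores) whose
items span ranges of difficulty and category count, for the study pipeline
that relates the eta1-eta2 discrepancy to scale discrepancy.

Difficulty of a k-category variable is mean/max, i.e. the proportion
correct for a binary item.  Quantile (equal-frequency) binning with a
target difficulty p != 0.5 tilts the cumulative cut probabilities through
a one-parameter power family (j/k)^alpha, with alpha solved so the
population mean label equals (k-1)p; alpha = 1 recovers uniform bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, skewnorm

from .exceptions import InvalidInputError
from .types import PairedSeries

__all__ = [
    "DiscretizationSpec",
    "TestCollectionSpec",
    "SimulatedTest",
    "normal_scores",
    "sample_latent",
    "discretize",
    "identical_pair_demo",
    "two_item_regression_demo",
    "generate_test_collection",
]

SCHEMES = ("equal_frequency", "equal_width", "binary_threshold")


@dataclass(frozen=True)
class DiscretizationSpec:
    """How to cut a latent vector into an observed ordinal variable.

    Parameters
    ----------
    n_categories
        Number of ordinal categories (>= 2).
    difficulty
        Target difficulty p = mean/max of the output, in (0, 1).
    scheme
        ``binary_threshold``: 1 iff the latent value exceeds its (1 - p)
        empirical quantile (requires ``n_categories == 2``).
        ``equal_frequency``: quantile bins labelled 0..k-1, tilted so the
        realized difficulty tracks ``difficulty``.
        ``equal_width``: k equal-length bins over the latent range
        (``difficulty`` is ignored; the latent shape decides it).
    """

    n_categories: int
    difficulty: float = 0.5
    scheme: str = "equal_frequency"

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise InvalidInputError("n_categories must be >= 2")
        if not 0.0 < self.difficulty < 1.0:
            raise InvalidInputError("difficulty must be in (0, 1)")
        if self.scheme not in SCHEMES:
            raise InvalidInputError(f"scheme must be one of {SCHEMES}")
        if self.scheme == "binary_threshold" and self.n_categories != 2:
            raise InvalidInputError("binary_threshold requires n_categories == 2")


def normal_scores(n: int) -> np.ndarray:
    """Deterministic standard-normal quantiles at (i − 0.5)/n, i = 1..n.

    A reproducible stand-in for a normally distributed latent sample,
    symmetric about zero for every n.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    return norm.ppf((np.arange(1, n + 1) - 0.5) / n)


def sample_latent(n: int, distribution: str = "normal", seed: int = 0) -> np.ndarray:
    """Random latent vector: standard normal or right-skewed (skew-normal a=5).

    Reproducible bit-for-bit under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if distribution == "normal":
        return rng.standard_normal(n)
    if distribution == "skew":
        return skewnorm.rvs(a=5.0, size=n, random_state=rng)
    raise InvalidInputError(f"unknown distribution {distribution!r}")


def _tilt_alpha(k: int, p: float) -> float:
    """Solve sum_j (j/k)^alpha = (k-1)(1-p) so the mean label is (k-1)p."""
    target = (k - 1) * (1.0 - p)
    j = np.arange(1, k) / k

    def f(alpha: float) -> float:
        return float(np.sum(j**alpha)) - target

    if abs(f(1.0)) < 1e-12:
        return 1.0
    return brentq(f, 1e-6, 60.0)


def discretize(latent: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    """Cut a latent vector into ordinal labels 0..k−1, preserving order.

    Sorted latent values map to non-decreasing labels; tied latent values
    always receive the same label.
    """
    latent = np.asarray(latent, dtype=float)
    if np.ptp(latent) == 0:
        raise InvalidInputError("latent vector is constant")
    n = len(latent)
    k = spec.n_categories
    if spec.scheme == "binary_threshold":
        p = spec.difficulty
        if p * n < 1 or (1 - p) * n < 1:
            raise InvalidInputError(
                f"difficulty {p} infeasible for n={n}: empty category"
            )
        threshold = np.quantile(latent, 1.0 - p)
        return (latent > threshold).astype(np.int64)
    if spec.scheme == "equal_frequency":
        if n < k:
            raise InvalidInputError(f"need at least k={k} observations")
        alpha = _tilt_alpha(k, spec.difficulty)
        cuts = (np.arange(1, k) / k) ** alpha
        edges = np.quantile(latent, cuts)
        return np.searchsorted(edges, latent, side="left").astype(np.int64)
    # equal_width
    edges = np.linspace(latent.min(), latent.max(), k + 1)[1:-1]
    return np.searchsorted(edges, latent, side="right").astype(np.int64)


def identical_pair_demo(
    n: int = 1000,
    item_spec: DiscretizationSpec = DiscretizationSpec(2, 0.10, "binary_threshold"),
    score_spec: DiscretizationSpec = DiscretizationSpec(7, 0.50, "equal_frequency"),
):
    """Discretize one shared latent vector into an item and a score.

    The latent correlation is 1 by construction, so every shortfall of the
    observed item-score correlation from 1 is mechanical deflation.  With
    the default specs (binary item at difficulty 0.10, seven-category
    equal-frequency score) the population correlation is 0.5 — a deflation
    of half a unit despite a perfect latent association — while the
    attenuation-corrected correlation recovers 1 exactly because the two
    discretizations are co-ordered.

    Returns the :class:`~dircorr.types.PairedSeries` and its
    :class:`~dircorr.attenuation.DeflationReport`.
    """
    from .attenuation import deflation_report

    latent = normal_scores(n)
    g = discretize(latent, item_spec)
    x = discretize(latent, score_spec)
    pair = PairedSeries(g, x)
    return pair, deflation_report(pair)


def two_item_regression_demo(n: int = 1000):
    """Two binary manifestations of one latent variable predicting a third.

    Builds g1 (difficulty 0.20), g2 (difficulty 0.80) and a seven-category
    score X from the same deterministic latent vector, computes the 3x3
    correlation table, and applies the two-predictor multiple-R closed
    form.  Even though all three variables share one latent image
    (pairwise latent correlations of 1), the observed multiple R is well
    below 1 — deflation carried into R².

    Returns ``(corr_table, R, R_squared)`` with ``corr_table`` a pandas
    DataFrame indexed by variable name.
    """
    from .estimators import multiple_r_two_predictors

    if n < 100:
        raise InvalidInputError("n must be >= 100 for a stable demo")
    latent = normal_scores(n)
    g1 = discretize(latent, DiscretizationSpec(2, 0.20, "binary_threshold"))
    g2 = discretize(latent, DiscretizationSpec(2, 0.80, "binary_threshold"))
    x = discretize(latent, DiscretizationSpec(7, 0.50, "equal_frequency"))
    frame = pd.DataFrame({"X": x, "g1": g1, "g2": g2}, dtype=float)
    table = frame.corr()
    r = multiple_r_two_predictors(
        table.loc["X", "g1"], table.loc["X", "g2"], table.loc["g1", "g2"]
    )
    return table, r, r**2


@dataclass(frozen=True)
class TestCollectionSpec:
    """Parameters of a simulated collection of tests.

    Each test draws a latent trait theta per person; each item draws a
    loading lambda, a difficulty and a category count, and responds with
    discretize(lambda*theta + sqrt(1-lambda²)*noise).  The score is the
    row sum of the items.  Defaults emulate an achievement-test item bank:
    tests of 2-30 items, 50-200 takers, item difficulties 0.24-0.95,
    category counts from binary up to 16, and loadings 0.45-0.90.
    """

    n_tests: int = 200
    n_persons_options: Sequence[int] = (50, 100, 200)
    n_items_range: tuple[int, int] = (2, 30)
    n_categories_range: tuple[int, int] = (2, 16)
    difficulty_range: tuple[float, float] = (0.24, 0.95)
    loading_range: tuple[float, float] = (0.45, 0.90)
    latent_distribution: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise InvalidInputError("n_tests must be >= 1")
        for name, (lo, hi) in (
            ("n_items_range", self.n_items_range),
            ("n_categories_range", self.n_categories_range),
            ("difficulty_range", self.difficulty_range),
            ("loading_range", self.loading_range),
        ):
            if lo > hi:
                raise InvalidInputError(f"{name} is empty: {(lo, hi)}")
        if self.n_categories_range[0] < 2:
            raise InvalidInputError("items need at least 2 categories")
        if not 0.0 < self.difficulty_range[0] <= self.difficulty_range[1] < 1.0:
            raise InvalidInputError("difficulty_range must lie in (0, 1)")
        if not (0.0 < self.loading_range[0] and self.loading_range[1] <= 1.0):
            raise InvalidInputError("loading_range must lie in (0, 1]")
        if not self.n_persons_options:
            raise InvalidInputError("n_persons_options must be non-empty")


@dataclass(frozen=True)
class SimulatedTest:
    """One simulated test: a persons x items response matrix and metadata."""

    responses: pd.DataFrame
    item_difficulties: np.ndarray
    item_categories: np.ndarray
    item_loadings: np.ndarray
    latent: np.ndarray

    @property
    def score(self) -> pd.Series:
        return self.responses.sum(axis=1)


def generate_test_collection(spec: TestCollectionSpec) -> list[SimulatedTest]:
    """Generate a reproducible collection of simulated tests.

    The same spec (including seed) yields a bit-identical collection.
    Binary items use the threshold cut at the requested difficulty;
    polytomous items use tilted equal-frequency binning, so realized
    difficulties track the requested ones up to discreteness.
    """
    rng = np.random.default_rng(spec.seed)
    tests: list[SimulatedTest] = []
    for _ in range(spec.n_tests):
        n_persons = int(rng.choice(np.asarray(spec.n_persons_options)))
        n_items = int(rng.integers(spec.n_items_range[0], spec.n_items_range[1] + 1))
        theta = sample_latent(
            n_persons, spec.latent_distribution, seed=int(rng.integers(2**31))
        )
        cats = rng.integers(
            spec.n_categories_range[0], spec.n_categories_range[1] + 1, size=n_items
        )
        diffs = rng.uniform(*spec.difficulty_range, size=n_items)
        loads = rng.uniform(*spec.loading_range, size=n_items)
        columns = {}
        for j in range(n_items):
            noise = rng.standard_normal(n_persons)
            manifest = loads[j] * theta + np.sqrt(1.0 - loads[j] ** 2) * noise
            k = int(cats[j])
            scheme = "binary_threshold" if k == 2 else "equal_frequency"
            # clip binary difficulty so neither category is empty
            p = float(np.clip(diffs[j], 1.5 / n_persons, 1 - 1.5 / n_persons))
            diffs[j] = p
            columns[f"item{j + 1:02d}"] = discretize(
                manifest, DiscretizationSpec(k, p, scheme)
            )
        responses = pd.DataFrame(columns)
        tests.append(
            SimulatedTest(
                responses=responses,
                item_difficulties=diffs,
                item_categories=cats.astype(np.int64),
                item_loadings=loads,
                latent=theta,
            )
        )
    return tests
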