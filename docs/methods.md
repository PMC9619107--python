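# Methods

## Estimand and conventions

All bivariate estimators operate on a `PairedSeries`: an ordinal item
g ∈ {0..R−1} paired with a metric score X, n ≥ 2, no missing values.
Moments are population moments (divide by n) throughout: the correlation
is invariant to the choice, and the point-biserial closed form
σ_g = √(p(1−p)) with p the proportion of 1s only holds in the population
form. Degenerate inputs (a constant variable, zero total sum of squares)
raise errors rather than returning 0, so a deflated-to-degeneracy estimate
can never masquerade as a genuine null result. Displayed values use
half-even rounding to 3 decimals; machine-readable output keeps full
precision.

## Core estimators

**PMC.** ρ_gX = σ_gX/(σ_g σ_X), clamped to [−1, 1] against floating-point
overshoot. **Point-biserial:** (X̄₁ − X̄₀)·σ_g/σ_X for binary g;
algebraically identical to PMC and kept as a separate operation because it
makes the sign rule explicit.

**Coefficient eta.** η = √(SS_between/SS_total) from the one-way
decomposition of one variable over the categories of the other.
Direction `g_given_X` decomposes X over the categories of g (the
measurement-modelling reading "the score explains the item");
`X_given_g` decomposes g over the distinct values of X. The decomposition
object enforces SS_between + SS_within = SS_total to 1e−9 relative
tolerance, with SS_between capped at SS_total to absorb floating-point
overshoot. For binary g, |PMC| = η_g|X exactly; for ordinal g,
|PMC| ≤ η_g|X, with equality only when the group means of X are exactly
linear in g. Both facts are enforced by the test suite across a thousand
randomized datasets each.

**Signed eta.** The usual eta formula reports a magnitude only. The sign
is taken as sign(X̄₁ − X̄₀) for binary g. No closed sign rule exists for
polytomous ordinal g, so this package takes the sign of PMC — a design
choice, documented here, coherent with PMC tracking η_g|X.

**Two-predictor multiple R.** The closed form
√((r_yx² + r_yz² − 2 r_yx r_yz r_xz)/(1 − r_xz²)), with |r_xz| = 1
rejected as collinear and a non-positive-semi-definite correlation triple
rejected (radicand outside [0, 1] beyond 1e−12). Only the two-predictor
form is provided; general multiple regression is out of scope.

## Ordinal pair statistics

All of γ, Somers' D and τ-b are functions of the classification of the
n(n−1)/2 unordered pairs into concordant (C), discordant (D), tied on g
only, tied on X only, tied on both. Counting is done on the R×C
contingency table with a two-dimensional suffix cumulative sum —
O(n log n + RC) — and the suite checks it exactly against an O(n²)
enumeration oracle.

- γ = (C−D)/(C+D).
- Somers' D, direction `g_given_X`: (C−D)/(pairs differing on g);
  `X_given_g`: (C−D)/(pairs differing on X); `symmetric`: (C−D) over the
  average of the two denominators (equivalently the harmonic mean of the
  two directional deltas). Note the direction naming is the one used by
  cross-table outputs in the psychometric literature — the denominator is
  restricted to pairs that differ on the *named-first* variable — which is
  the mirror image of some textbook conventions. The bundled worked
  dataset (A1 → 1, 0.579, 0.408) locks the mapping, and scipy's
  `somersd` cross-checks it.
- τ-b = (C−D)/√(product of the two D denominators): the signed geometric
  mean of the directional deltas.
- Spearman ρ: PMC of mid-ranks (average ranks for ties).
- Item–rest correlation: PMC(g, X−g), requiring X to be a sum score
  containing g.

No standard errors or significance tests are attached to these
statistics; they are used as deflation-robust benchmarks, not as
inferential tools.

## Attenuation correction

With margins fixed, the covariance is maximal when g and X are
independently sorted into the same ascending order (rearrangement
inequality), so `max_pmc` is PMC of the sorted copies; it is deterministic
under permutations of tied values, and the suite verifies it against
exhaustive enumeration of all rearrangements at small n.
R_AC = ρ_obs/ρ_max, applied to magnitudes with the observed sign
reattached (negative associations correct toward −1; the construction was
developed for positively keyed items). E_AC divides the observed η_g|X by
eta of the sorted copies; that independent ordering *defines* the maximal
eta here — it provably dominates in the binary case (where it coincides
with max_pmc) and a 2,000-dataset empirical sweep in the suite found no
polytomous counterexample. A descending option exposes the minimal
(most negative) attainable correlation; note the anti-sorted value is not
in general −ρ_max when X is asymmetric.

The per-pair deflation report tabulates every observed estimator, the
corrected values, and deflation = (R_AC − |ρ_obs|)/R_AC. Because
R_AC = ρ_obs/ρ_max, this reduces per pair to 1 − ρ_max: an already
co-ordered item deflates by exactly the distance of its ceiling from 1.

## Simulation design

`normal_scores(n)` — Φ⁻¹((i−0.5)/n) — is the default latent vector: fully
deterministic, symmetric about 0, so the demonstrations are exactly
reproducible without a seed. Sampled latents (normal or skew-normal with
shape 5, for exploring distribution shape as a deflation factor) are
available behind explicit seeds.

Discretization preserves the latent order, mapping ties to a common
label. `binary_threshold` scores 1 above the (1−p) empirical quantile,
realizing difficulty p to within 1/n. `equal_frequency` cuts at quantiles;
when the target difficulty differs from 0.5 the cumulative cut
probabilities are tilted through the one-parameter family (j/k)^α with α
solved (bisection) so the population mean label is (k−1)p. α = 1 recovers
uniform bins, which is what the identical-latent demo uses for its
7-category score at p(X) = 0.50 (σ_X = 2 exactly in population).
`equal_width` bins the latent range and lets the latent shape set the
difficulty.

**Identical-latent demo.** Item (2 categories, p = 0.10, threshold) and
score (7 categories, equal frequency) cut from one vector of 1,000 normal
scores. Population algebra: the top decile lies entirely in the top score
septile, so σ_gX = 0.6 − 0.1·3 = 0.3, σ_g = 0.3, σ_X = 2, ρ = 0.5. The
demo reproduces 0.500 within 0.01 (discreteness of n = 1,000) and
R_AC = 1 exactly. Moving the item difficulty toward 0.5 strictly raises
the observed correlation.

**Two-item regression demo.** g₁ (p = 0.20) and g₂ (p = 0.80) from the
same latent as a 7-category score; population r(g₁,g₂) = 0.25
(cov = 0.2 − 0.16, σ = 0.4 each). Feeding observed correlations into the
two-predictor formula shows the deflation inherited by R². The quantile
construction gives r(X, g) ≈ 0.678 analytically; random-sampling recipes
give values in the 0.55–0.70 range depending on the draw, so the demo
asserts only the deterministic values.

**Test collections.** A collection is a list of simulated tests: per test,
n ∈ {50, 100, 200} persons each with latent θ; per item, a loading
λ ∈ [0.45, 0.90], a difficulty in [0.24, 0.95], and a category count in
2–16; the response is the discretization of λθ + √(1−λ²)·ε, ε standard
normal, and the score is the row sum. These ranges emulate an achievement
item bank in which most items are binary-to-few-category and item–score
correlations for binary items land around 0.3–0.6. The single-factor
linear model with independent item noise is deliberately simple: it
reproduces the *mechanical* phenomena under study (deflation by
discretization, the η₂−η₁ discrepancy rising with C/R) but not
item-level misfit, multidimensionality, or the person-level dependencies
of real response data — passing trend tests therefore demonstrate the
mechanism, not distributional realism. The default study size is 200
tests (≈3,000 items), which gives stable bin means while the whole
pipeline runs in a few seconds.

## Study pipeline

`item_analysis_table` computes, per item: difficulty, variance, observed
degrees of freedom df(g) and df(X) (distinct categories minus one — the
*realized* counts, since theoretical ranges are not recoverable from a
response matrix), C/R = (df(X)+1)/(df(g)+1), rit, η₁ ≡ η_g|X,
η₂ ≡ η_X|g, diff = η₂ − η₁, and the corrected estimators. Degenerate
items are flagged, not dropped, with estimators recorded as NaN. Rows
where η₁ > η₂ are flagged rather than forbidden (possible for wide item
scales).

`binned_difference_summary` reports mean/SD/count of diff per bin of
df(g) or C/R ((a, b] intervals over user-supplied edges, with a preset
ladder of C/R edges from below 1.929 up to above 14), plus a Spearman
trend statistic of bin index against bin mean. On the seeded default
collection the diff means decrease strictly across df(g) = 1..≥6 and rise
across the C/R ladder with trend ≈ 0.99.

Effect sizes: one-way F from the package's own SS decomposition (p-value
from scipy's F distribution), η² = SS_between/SS_total,
Cohen's f = √(η²/(1−η²)) (the standard conversion, verified to round-trip
to 1e−9), Cohen's d = mean difference / SD. Post hoc comparisons use
Welch (unequal-variance) t-tests — a deliberate choice, as bin variances
differ strongly — with Šidák adjustment 1 − (1−p)^m and per-comparison
threshold 1 − (1−α)^(1/m).

## Numerical choices and limitations

- Correlations are clamped to [−1, 1]; SS_between to [0, SS_total]. Ties
  in quantile edges can make equal-frequency bins uneven when the latent
  has mass points; with continuous latents realized difficulty is within
  1/n of target.
- eta is meaningful for *ordinal* g only; `ss_decomposition` accepts any
  integer grouping but the signed eta refuses nothing explicitly beyond
  its documented pmc-sign convention — interpretation with nominal g is
  the caller's responsibility.
- The B3 column of the bundled dataset is asserted at the
  enumeration-consistent γ/D values (0.720/0.698/0.364); its symmetric
  delta 0.479 confirms the underlying pair counts (C − D = 67).
- No polychoric/biserial latent-correlation estimation, no IRT response
  models, no reliability coefficients, no decision-tree bin mining: bin
  edges are user-supplied.
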