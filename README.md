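# dircorr

Directional association measures and deflation-corrected correlation for
item analysis and general bivariate settings.

## The problem

The product–moment correlation (PMC, Pearson's r) is usually treated as a
symmetric measure of association. When one variable g has a narrow ordinal
scale (an item scored 0/1 or 0..R−1) and the other X has a much wider
metric scale (a sum score, a continuous measure), that symmetry breaks
down in two ways:

1. **Directionality.** For binary g, PMC equals coefficient eta in exactly
   one direction — η_g|X, the values of X grouped by the categories of g
   ("the score explains the response pattern in the item") — and not the
   other (η_X|g). For polytomous ordinal g the relationship loosens to an
   inequality, |PMC| ≤ η_g|X, with PMC still tracking η_g|X far more
   closely than η_X|g. Whoever interprets r² as a symmetric "explained
   variance" is implicitly committing to one direction.
2. **Deflation.** With the observed values of g and X fixed, the variances
   are fixed, so the correlation is bounded by the value attained when both
   variables are sorted into the same order:
   ρ_max = σ_gX^max / (σ_g σ_X). A difficult binary item against a
   many-valued score cannot reach r = 1 no matter how perfect the latent
   association is; the shortfall is mechanical, not sampling error.

`dircorr` implements the estimators needed to see and quantify both
effects:

- **Core estimators** — PMC (population moments), the point-biserial
  closed form (X̄₁ − X̄₀)·σ_g/σ_X, coefficient eta in both directions via
  the between/within sum-of-squares decomposition, a signed eta, and the
  two-predictor multiple correlation
  R = √((r_yx² + r_yz² − 2 r_yx r_yz r_xz)/(1 − r_xz²)).
- **Ordinal pair statistics** — exhaustive concordant/discordant/tie
  counts, Goodman–Kruskal γ = (C−D)/(C+D), Somers' D in three directions,
  Kendall τ-b, Spearman ρ, item–rest correlation.
- **Attenuation correction** — the maximal correlation ρ_max under the
  observed margins, R_AC = ρ_obs/ρ_max, E_AC = η_obs/η_max, and a
  per-pair deflation report.
- **Simulation** — deterministic normal scores, latent discretization
  (threshold, equal-frequency and equal-width schemes with a target
  difficulty), the identical-latent deflation demonstrations, and a
  generator of whole collections of simulated tests.
- **Study pipeline** — per-item estimator tables, the η₂ − η₁ discrepancy
  summarized over bins of item degrees of freedom or of the C/R
  scale-discrepancy ratio, one-way effect sizes (F, η², Cohen's f and d)
  and Šidák-adjusted pairwise comparisons.

## Worked example

The package bundles a 20-person, 6-item dataset built to expose the
directionality (three binary items A1–A3, three polytomous items B1–B3,
score X). For the deterministic polytomous item B1:

```sh
$ dircorr associate worked-example -g B1 -x X
n: 20
categories_g: 5
categories_X: 17
difficulty_p: 0.150
pmc: 0.747
eta_g_given_X: 0.820
eta_X_given_g: 1.000
gamma: 1.000
somers_d_g_given_X: 1.000
...
```

B1 follows the score deterministically, and the tie-insensitive measures
(γ and D directed "g given X") say so: 1.000. PMC reports 0.747 and
η_g|X 0.820 — not because the association is imperfect but because the
5-category item cannot co-vary linearly with a 17-valued score. Note the
directionality: η_g|X = 0.820 ≠ η_X|g = 1.000, and PMC sides with the
former.

The deflation report for the error-laden binary item A3 quantifies the
ceiling:

```sh
$ dircorr deflation worked-example -g A3 -x X
observed.pmc: 0.117
corrected.max_pmc: 0.759
corrected.r_ac: 0.154
summary.deflation_percent: 0.241
...
```

Under A3's margins (five 1s against this score) no arrangement can
correlate above 0.759, so the observed 0.117 is 15.4% of what is
attainable, and even a perfectly ordered arrangement would lose 24.1% of
a unit correlation to the scale mismatch.

The same mechanism, isolated analytically: cut one latent vector of 1,000
normal scores into a binary item at difficulty p = 0.10 and a 7-category
equal-frequency score. The latent correlation is 1 by construction, yet

```python
>>> import dircorr as dc
>>> pair, report = dc.identical_pair_demo(n=1000)
>>> round(report.observed["pmc"], 3), round(report.corrected["r_ac"], 3)
(0.5, 1.0)
```

PMC loses half a unit of correlation to discretization alone; R_AC
recovers the co-ordering exactly.

Library surface: `pmc`, `point_biserial`, `eta`, `eta_signed`,
`eta_squared`, `ss_decomposition`, `multiple_r_two_predictors`,
`pair_counts`, `gamma`, `somers_d`, `kendall_tau_b`, `spearman_rho`,
`item_rest_correlation`, `max_pmc`, `r_ac`, `max_eta`, `e_ac`,
`deflation_report`, the simulators in `dircorr.simulate`, and the study
pipeline in `dircorr.study`. CLI subcommands: `associate`, `deflation`,
`item-analysis`, `simulate`, `study`.

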