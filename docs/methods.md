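# Methods

## The analysis chain

The package models a routine cross-sectional mental-health screening survey
of college freshmen. Four instruments are scored by plain item sums: the
PHQ-9 depression screener (9 items, 0–3, total 0–27, banded at 5/10/15/20
into mild / moderate / moderately severe / severe), the SCL-90
interpersonal-sensitivity subscale (9 items, 0–4), the PCQ-24 psychological
capital composite (24 items, 1–6), and a 20-item yes/no family-support scale.
A missing item voids the scale total; incomplete questionnaires are excluded
rather than pro-rated, mirroring the intake practice the pipeline emulates.

The substantive model is a moderated moderation: with Y = depression,
X = interpersonal sensitivity, M = psychological capital, W = family support,
all standardized before products are formed,

    Y = b0 + b1 X + b2 M + b3 XM + b4 W + b5 XW + b6 MW + b7 XMW + ε.

Standardize-then-multiply is deliberate: it makes the ±1 SD simple-slope
algebra exact, so the four corner slopes are b1 ± b3 ± b5 ± b7 and every
pairwise slope difference is a linear contrast of (b3, b5, b7). The
alternative (standardizing the product terms themselves) cannot reproduce the
contrast arithmetic of the reported slope tables.

## Estimation and inference

OLS is computed via a QR factorisation (no normal-equations squaring);
rank-deficiency is detected from the R diagonal and reported with the
offending column names. Standard errors come from σ̂²(XᵀX)⁻¹ with
σ̂² = RSS/(n−k−1); coefficient tests and confidence intervals use the
t(n−k−1) reference (at n = 694 the 97.5% quantile is ≈1.9635 vs the normal
1.96 — below reporting precision, but kept for internal consistency).
R² and F = (R²/k)/((1−R²)/(n−k−1)) round out the fit summary.

Slope-difference tests use the standard-normal reference with the 1.96
multiplier for 95% intervals, the convention of the slope-difference
procedure for probing three-way interactions; the t-based alternative differs
only in the fourth decimal at the relevant sample sizes. Simple-slope and
slope-difference standard errors are contrast forms √(cᵀVc) on the full
coefficient covariance matrix.

A fit object can also be desk-constructed from a printed coefficient vector
(`ModelFit.from_coefficients`); contrast point estimates are then exact while
standard errors are undefined (NaN) unless a covariance matrix is supplied.

## Synthetic cohorts

The generator is latent-first. (X, M, W) are drawn from a zero-mean
unit-variance trivariate normal with configurable correlations (defaults
−0.361, −0.286, 0.229 for IS–PsyCap, IS–FS, PsyCap–FS); Y follows the
equation above with the configured b-vector (defaults are the fitted values
b = −0.058, 0.343, −0.006, −0.106, −0.033, −0.032, 0.011, 0.076) and
ε ~ Normal(0, 0.8). These defaults reproduce, by construction, the observed
score-table correlations to within ±0.01 analytically (e.g. the implied
corr(X, Y) is 0.392 against the observed 0.399).

Latent scores map to bounded integer totals at the configured means/SDs
(defaults: Dep 7.909/3.147, IS 14.442/6.148, PsyCap 102.107/13.064, FS
13.895/4.833 — the screened-sample values). Because instruments are bounded,
a latent normal placed at the target moments is censored at the floors and
ceilings; near a ceiling this visibly shrinks the realized SD (family
support, mean ≈14 on a 0–20 scale, loses ≈9% of its SD). The generator
therefore inverts the censoring: it solves, per scale, for the latent
(μ, σ) whose clipped-normal moments equal the configured targets
(closed-form censored-normal moments, scipy root solve). Where clipping is
negligible the solution collapses to the targets themselves.

Each total is then spread over the instrument's items by a multivariate
hypergeometric allocation — uniform over all item vectors with exactly that
sum. This preserves totals exactly (all the downstream analysis uses) and is
deliberately agnostic about item-level structure: no item-response model, no
ordinal polychoric structure, no per-item difficulty. Consequently item-level
statistics (Cronbach's α of generated cohorts, Harman shares) are emergent
rather than calibrated, and passing tests say nothing about item-level
realism of real surveys.

The outcome scale deserves one note. With ε SD 0.8 the equation yields a
latent Y with SD ≈ 0.905 (computed exactly via Isserlis moment identities in
`equation_moments`, which also feeds the total mapping). Refitting on the
latents recovers the configured b-vector directly; refitting the fully
standardized model on cohort totals recovers b/σ_Y, since restandardizing the
outcome rescales every coefficient by 1/σ_Y ≈ 1.10. Parameter-recovery
checks therefore run on the latent draw, correlation round-trips on the
item-level cohort.

Gender is assigned independently of all scores (59.65% female by default),
matching the absence of gender differences in the population emulated.

### Contamination

Contaminated records exercise the exclusion rules; class counts are exactly
round(rate·n), and sub-streams of the root seed ensure adding contamination
never perturbs clean records. The three concrete proxies for qualitative
exclusion criteria are:

* **incomplete** — one to three randomly blanked items;
* **straight_line** — the same response on every item of all three
  polytomous instruments (PHQ-9, IS, PCQ-24). The binary family-support
  scale is excluded from the detection rule: all-"yes" is a plausible honest
  answer (≈12% of honest synthetic records sit at the FS ceiling), and
  honest all-zero PHQ-9 and IS responses co-occur often enough that any
  two-instrument rule would misfire on clean records, while an honest
  constant PCQ-24 (24 identical 6-point answers summing to the target total)
  has negligible probability;
* **patterned** — a strict two-value alternation across the two long
  instruments (PCQ-24 and FS-20). Short instruments are skipped because a
  nine-item alternation arises by honest chance too often to be diagnostic.

Detection and generation use the same predicates, so exclusion counts are
exact and idempotent.

`cohort_with_band_counts` builds intake-style fixtures with prescribed
severity-band counts: a clean cohort is ranked by depression total and each
record's total is clipped into the band assigned to its rank, preserving the
ordering (hence the correlation structure) while pinning the counts exactly.

## Screening statistics

Prevalence is 100·(positives among retained)/retained, with positives at
PHQ-9 ≥ 5. Pearson correlations carry two-sided p from t = r√((n−2)/(1−r²)).
The gender comparison is Student's pooled-variance two-sample t (two-sided);
Welch is available behind a flag. Harman's single-factor test takes the first
eigenvalue share of the pooled standardized item correlation matrix (the
first unrotated principal component — the deterministic and dominant
convention); a scale-level entry point (`harman_from_scores`) is provided,
item-level pooling being the default. Reliability uses the population
variance convention (the choice cancels exactly for α; it moves KR-21 in the
fourth decimal at survey n).

## Monte-Carlo power

Each replicate draws fresh standardized trivariate-normal predictors at the
configured correlations (`simulate_mvn`; `fixed_design` instead freezes one
predictor matrix and resamples only residuals), forms Y from the equation,
fits the full eight-term model, and tests the scenario's coefficient — XM for
scenario A (grid −0.03…−0.12, XMW held at 0.076), XMW for scenario B (grid
0.01…0.10, XM held at −0.106) — at α = 0.05 with the same t(n−k−1) reference
as the estimation module. Defaults: n = 694, 1,000 replicates.

Implementation note: only the tested coefficient moves along the grid, and
adding e·(tested column) to the outcome shifts the tested estimate by exactly
e while leaving residuals and standard errors unchanged; each replicate is
therefore fitted once with the tested coefficient at zero and the whole grid
evaluated analytically. Replicate sub-seeds are spawned from the scenario
seed and shared across grid points (common random numbers), so each point is
individually reproducible and the curve is smooth in the effect size.

### A known, quantified limitation

Power for the three-way term depends on the partial variance of the XMW
column after the other seven regressors. Under trivariate-normal predictors
at the configured correlations this is ≈1.29 (and ≈1.16–1.17 under
discretized or screen-truncated synthetic predictors), giving ≈75% power at
b7 = 0.076. The original survey's design matrix had heavier-tailed products:
back-solving its printed coefficient standard errors gives a partial XMW
variance of ≈1.56 and an implied power of ≈88% — the reported value. No
synthetic predictor model consistent with the published moments reproduces
that sixth-moment excess, so the package reports the lower, internally
consistent figure rather than tuning toward the published one. The two-way
term is insensitive to this (its partial variance nearly matches), and the
simulated power (~91–93%) brackets the reported 90.8%.

## Numerical and degenerate-input choices

Standardization uses the n−1 (sample) SD; at analysis sample sizes the n
convention differs below reporting precision. Zero-variance variables raise
a degenerate-variable error everywhere (standardization, correlations,
reliability) rather than propagating NaN. Exact fits (R² = 1) report F = ∞.
Totals outside a scale's feasible range are clipped before item allocation,
which is what makes boundary totals (0 → all items 0) deterministic. Display
rounding is 3 decimals in text reports; stored JSON/CSV artifacts keep full
precision, and every pipeline artifact is stamped with a configuration hash
and the seed.

## Default problem sizes

Tests and the acceptance script use the study-scale defaults where the
quantity is study-anchored (n = 694, 1,000 replicates for power; the
2,359-record intake fixture) and modest cohorts elsewhere (n = 5,000 for
moment/correlation round-trips, a single n = 50,000 latent draw for
coefficient recovery) — sizes at which Monte-Carlo error is comfortably
inside the stated tolerances.
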