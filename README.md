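# modmod

Moderated-moderation analysis of mental-health screening surveys.

`modmod` implements, end to end, the analysis chain used to study how the
effect of interpersonal sensitivity (IS) on depressive symptoms (Dep) among
college freshmen is moderated by psychological capital (PsyCap), and how that
moderation is itself moderated by perceived family support (FS):

* scoring of the four instruments (PHQ-9, the SCL-90 interpersonal-sensitivity
  subscale, PCQ-24, and a 20-item binary family-support scale), with severity
  banding, Cronbach's α and KR-21 reliability;
* record exclusion (incomplete / straight-line / patterned responding),
  positive-screen selection (PHQ-9 total ≥ 5), descriptives, Pearson
  correlations, gender t-tests, and Harman's single-factor test;
* standardized two-way and three-way interaction OLS fitted from first
  principles, with full inferential output;
* simple slopes at ±1 SD of both moderators and all six pairwise
  slope-difference z-tests;
* Monte-Carlo power for the two-way and three-way interaction coefficients;
* a synthetic cohort generator reproducing the survey's statistical structure,
  so every stage is testable without raw data.

## The model

With all variables standardized and products formed afterwards, the three-way
("moderated moderation") model is

```
Y = b0 + b1 X + b2 M + b3 XM + b4 W + b5 XW + b6 MW + b7 XMW + ε
```

where Y = Dep, X = IS, M = PsyCap, W = FS. The conditional (simple) slope of
X at moderator values (m, w) is `b1 + b3 m + b5 w + b7 m w`; at the four
(±1 SD, ±1 SD) corners these are the four reported slopes, and each pairwise
difference is a linear contrast of (b3, b5, b7) tested against the standard
normal with `se = √(cᵀVc)` (the slope-difference procedure for three-way
interactions). Power is estimated by simulation: draw standardized predictors,
form Y from the equation with Normal(0, 0.8) residuals, refit, and count
rejections of the tested coefficient at α = 0.05.

## Worked example

Slope probing from a fitted coefficient table (b1 = 0.343, b3 = −0.106,
b5 = −0.032, b7 = 0.076):

```python
from modmod import (DEFAULT_COEFFICIENTS, ModelFit, simple_slopes,
                    slope_difference_tests, slope_table)

fit = ModelFit.from_coefficients(DEFAULT_COEFFICIENTS, n=694)
print(simple_slopes(fit).as_frame())
print(slope_table(slope_difference_tests(fit)))
```

```
                  label  slope
1  high PsyCap, high FS  0.281
2   high PsyCap, low FS  0.193
3   low PsyCap, high FS  0.341
4    low PsyCap, low FS  0.557
       pair  difference
(1) and (2)       0.088
(1) and (3)      -0.060
(1) and (4)      -0.276
(2) and (3)      -0.148
(2) and (4)      -0.364
(3) and (4)      -0.216
```

The X→Y slope is steepest for low-PsyCap/low-FS respondents (0.557) and
flattest when both resources are high (0.281); differences involving corner 4
are the large ones, i.e. family support matters most when PsyCap is low.

An intake-to-report run on synthetic data — a cohort of 2,359 records with
112 contaminated and a prescribed severity breakdown — reproduces the intake
arithmetic:

```python
from modmod import cohort_with_band_counts, screening_report

cohort = cohort_with_band_counts(
    {"none": 1553, "mild": 591, "moderate": 70,
     "moderately_severe": 23, "severe": 10},
    {"incomplete": 48, "straight_line": 36, "patterned": 28},
    seed=1,
)
report, scores = screening_report(cohort)
# raw=2359 excluded=112 (4.75%) retained=2247 positive=694 prevalence=30.89%
```

Fitting the three-way model on a clean synthetic analysis sample (n = 694,
seed 1) recovers the generating structure within sampling noise:

```
       coefficient     se      t      p   llci   ulci
const       -0.062  0.037 -1.662  0.097 -0.136  0.011
x            0.341  0.039  8.757  0.000  0.265  0.418
m           -0.060  0.039 -1.524  0.128 -0.136  0.017
xm          -0.081  0.037 -2.180  0.030 -0.154 -0.008
w            0.011  0.038  0.289  0.773 -0.064  0.086
xw          -0.072  0.040 -1.825  0.068 -0.150  0.005
mw           0.050  0.038  1.295  0.196 -0.026  0.125
xmw          0.088  0.034  2.609  0.009  0.022  0.154
R2=0.195 F=23.670 n=694
```

and Monte-Carlo power for the two-way term at its fitted value −0.106
(n = 694, 1,000 replicates) comes out at ~92% (MC se ≈ 0.8 points).

## Command line

```sh
modmod simulate --config examples/pipeline.yaml --out cohort.csv
modmod score    --in cohort.csv --out scores.csv
modmod screen   --in cohort.csv --report screening.json
modmod fit      --in scores.csv --model 3 --out fit.json
modmod slopes   --fit fit.json --out slopes.csv
modmod power    --scenario A --out power_a.csv
modmod all      --config examples/pipeline.yaml
```

Exit codes: 0 success, 2 validation/configuration error, 3 missing upstream
artifact.

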