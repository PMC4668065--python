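# Methods

## Scoring and grading rule engines

The six-parameter oocyte score sums four observer-judged ordinal levels
(morphology, cytoplasm, PVS, polar body; worst/average/best → −1/0/+1) and
two banded measurements. The published band descriptions leave the middle
band implicit ("did not deviate from normal by more than 10 µ" for diameter,
"2 µ" for zona thickness, without a numeric "normal"); we close the gaps by
taking the 0-band as the closed complement of the −1 and +1 bands —
[120, 130] ∪ [150, 160] µm for diameter and [10, 12] ∪ [18, 20] µm for zona
thickness — so boundary measurements take the middle score and the three
bands partition the positive reals with no overlap. Categorical levels are
accepted as already-judged inputs; the package deliberately models the
scoring arithmetic and statistics, not image interpretation. All thresholds
are in microns with no unit auto-detection.

The day-3 grade cascade is evaluated from Grade 5 downward with the clinical
cell ranges ("6–8", "4–8") read as minimum-cell conditions (≥6, ≥4) and
fragmentation boundaries assigned so the first matching rule wins:
G5 = ≥8 cells & <5 %; G4 = ≥6 & ≤5 %; G3 = ≥6 & ≤20 %; G2 = ≥4 & ≤40 %;
everything else (including <4-cell or arrested embryos) falls to Grade 1.
This totalizes the published assignments while keeping the map monotone
(never worse with more cells, never better with more fragmentation). Note a
side effect of the cascade: an ≥8-cell embryo can only receive Grade 4 at
exactly 5 % fragmentation. The Grade-1 fallback for <4-cell embryos is this
package's choice, not a published rule.

PTOS is the mean TOS over all scored mature oocytes of the cycle (≥2
required); an option restricts the average to oocytes whose embryos were
transferred, for the transfer-restricted sensitivity analyses.

## Synthetic cohort generator

The generator emulates a hierarchical ICSI cohort: patients (age
truncated-normal 36.6 ± 7.3 y on [18, 52]; oocyte yield negative-binomial
matched to mean 7.97, SD 5.76 — SD ≈ mean argues overdispersion — truncated
at ≥2), oocytes, one day-3 embryo per scored oocyte (fertilization failure
is not modelled; the emulated analysis set carried every mature oocyte
through to day 3), best-grade-first transfer of 2.53 ± 1.06 embryos
(clipped to [1, 7] and to the available count), and a cycle-level pregnancy
outcome.

Parameter levels: each oocyte has a latent Gaussian quality loaded on a
patient latent (defaults 0.5 within-oocyte, 0.3 within-patient — moderate
positive values chosen so the clustered models have something real to
correct for; the study quantifies neither correlation). Each parameter's
level is a thresholded Gaussian copula draw, so the configured marginals
(defaults: the study's observed per-parameter score distribution) hold
exactly in expectation. Diameter and ZP values are then drawn uniformly
inside the micron band of the drawn level, which makes re-scoring the table
reproduce the levels. An optional `yield_quality_loading` couples yield and
quality (off by default).

Embryo and pregnancy outcomes are drawn from *marginal* models on purpose:
P(≥8 cells) = logit⁻¹(b0 + ln(1.12)·TOS + age_slope·(age − 36.6)) and a
proportional-odds model for grade with slope ln(1.19)·TOS; within-patient
dependence enters through a Gaussian copula on the outcome uniforms
(`cluster_sd`, default 0.5) rather than a logit-scale random intercept. A
conditional intercept would attenuate the population-averaged odds ratio —
the estimand a GEE reports — below the configured value; with the copula
construction the configured ORs are exactly the marginal ones, which is what
the parameter-recovery tests check. The two embryo outcomes share one
uniform per embryo (comonotone), so quality is coherent across scales and
the infeasible pair (Grade 5, <8 cells) is essentially impossible under the
default calibration (residual cases are promoted to 8 cells and counted in
the ground truth). Cell count and fragmentation are back-filled uniformly
within the band consistent with the drawn grade and eight-cell flag; ≥8-cell
counts follow the emulated 8/10/12-cell mix.

Intercepts are calibrated, not guessed: b0 and the pregnancy intercept γ0
are solved by root-finding so the mean predicted probability over the
realized covariates equals the configured base rate (0.645 for ≥8 cells) and
prevalence target (0.31). Pregnancy (OR 1.58 per PTOS point, age-adjusted)
is drawn per cycle; gestational sacs are 0 if not pregnant, else
1 + Binomial(transferred − 1, logit⁻¹(−1.5 + 0.4·PTOS)) — consistent with
the definition of clinical pregnancy as ≥1 sac, and producing tertile
implantation rates that rise with PTOS (a qualitative, not numeric,
calibration; the published tertile rates come from data the generator does
not see). Grade cutpoints (−2.05, −1.06, −0.20, 0.79) were set once from the
emulated grade mix (≈54 % Grade ≥4).

What the generator does **not** emulate: fertilization failure and embryo
arrest before day 3, donor-oocyte age structure, stimulation covariates
(FSH, AMH, diagnosis), inter-observer scoring disagreement, and any
selection between retrieval and scoring. Tests passing on synthetic cohorts
therefore validate the estimators and plumbing — that effects put in are
recovered with correct coverage — not clinical effect sizes on real data.

## Statistical models

Embryo-level models are population-averaged GEE fits clustered by patient
with sandwich SEs: binary logit (exchangeable working correlation by
default) for the ≥8-cell outcome; proportional-odds cumulative logit with
independence working correlation for the 5-level grade (the standard
estimable choice for clustered ordinal data; exchangeable ordinal GEE is out
of scope, and with two outcome levels the fit collapses exactly to the
binary model). Categorical characteristics are treatment-coded against the
worst level (−1). The ordinal design carries no intercept — the cutpoints
play that role — and constant predictors, which the cutpoints absorb, are
reported as slope 0 with infinite SE rather than crashing.

Cycle-level fits are ordinary ML: binary logistic for pregnancy on PTOS
(age-adjusted by default; a "multinomial" pregnancy model with two classes
is the same thing), OLS for mean available-embryo grade on PTOS, and a
binomial GLM of (sacs, transferred − sacs) on tertile + age with a Wald test
of the tertile terms for the overall p. Age is the default adjustment
covariate throughout; BMI/race can be passed as extra columns but are not
defaults. Tertiles are equal-count rank splits with ties broken by
patient id (a quantile-threshold mode is available). All intervals are 95 %
Wald on the estimation scale; reported ORs are exp(coefficient).

The AUC is the frequency-weighted pairwise concordance (ties ½), identical
to the trapezoidal area under the empirical ROC curve; SEs and the paired
test use DeLong structural components, with integer weights reproducing
replication exactly (weight = embryos transferred implements the weighted
ROC variant). The embryo-side predictor defaults to the mean grade of
transferred embryos (max-grade by flag); the oocyte side defaults to PTOS
over all scored oocytes (transfer-restricted by flag). The good-quality
restriction keeps cycles with at least one transferred embryo of Grade ≥4
by default; an "all transferred ≥4" reading is selectable, since the
published description does not disambiguate. Degenerate comparisons
(identical scores) return z = 0, p = 1; a class with total weight ≤1
contributes zero variance.

## Numerical and design notes

* Determinism: one `numpy` Generator seeded from the config; identical
  config + seed reproduces all tables and the whole results bundle byte for
  byte.
* Separation in logistic/GEE fits is flagged when a coefficient diverges
  (|β| > 15) and raised as a degenerate-outcome error naming the terms.
* Problem sizes in the test suite — 100 replicates for coverage checks at
  400–1,000 patients, 1,000 replicates for the DeLong size check at 100
  cycles, 20,000 oocytes for marginal calibration — were chosen as the
  smallest sizes at which the binomial tolerances of those checks are
  comfortably discriminating.
* Rows with missing model fields are dropped before fitting; no imputation.
* The spec'd command surface (`simulate`, `score`, `grade`, `fit`, `roc`,
  `run-all`) is a thin click layer over the library; every analysis is
  available as a plain function call.

## Known limitations

Real grading systems differ between laboratories; the cascade here encodes
one center's day-3 scheme. The proportional-odds assumption for grade is a
modelling choice the published single-OR summary cannot adjudicate. The
generator's implantation process is only qualitatively linked to PTOS.
Published headline estimates from the original 94-patient dataset (its AUCs
and exact ORs) depend on unavailable raw data and are emulated as generator
inputs, not reproduced as outputs.
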