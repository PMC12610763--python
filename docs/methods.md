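# Methods

`riskoverlap` implements a threshold-based comparison of three ways of
flagging women as being at high five-year risk of breast cancer — a
polygenic risk score (PRS), the parsimonious Gail model, and binary
first-degree family history (FH) — in retrospective case-control cohorts
stratified by genetic ancestry (European, Asian), age group (<50, ≥50
years), and disease type (invasive breast cancer, DCIS). This note records
the models, the numerical choices, and what the synthetic cohorts do and do
not establish.

## Absolute-risk projection

Both risk engines share one projection primitive. Given a relative risk
`rr`, age-banded breast-cancer incidence hazards `h1` and competing
(non-breast-cancer) mortality hazards `h2` (per person-year), the
probability of a breast-cancer event within a horizon `T` (default 5 years)
from age `a` is the two-state competing-risks integral

    AR = ∫ₐ^{a+T} rr·h1*(t) · exp(−∫ₐ^t (rr·h1*(u) + h2(u)) du) dt,

evaluated in closed form per band because the hazards are piecewise
constant: band k of length L_k contributes
`S_k · λ_k/(λ_k+h2_k) · (1 − exp(−(λ_k+h2_k)L_k))` with
`λ_k = rr·h1*_k` and `S_k` the survival to the band start. Bands with
`λ_k + h2_k = 0` contribute nothing. No quadrature is involved; the result
is exact for banded tables, and the test suite checks agreement with an
independent high-order ODE integration to a relative error of 1e−8 on
randomized tables.

For the Gail engine, `h1* = h1·(1−AR)`, the attributable-risk complement
that converts composite population incidence into baseline incidence for an
all-reference-covariates woman; two age-regime values (<50 / ≥50) are
carried in the rate table. For the PRS engine no `1−AR` factor applies;
its baseline is set by the population-mean constraint described below.

The packaged rate tables (`White`, `Chinese`; 5-year bands covering
[20, 90)) are transcriptions representative of the published rates behind
standard Gail-type software, shipped so the package runs self-contained.
They are research fixtures: any table with the same six-column schema can
be substituted, and should be for clinical work. Coverage to age 90 means a
five-year projection is defined for every included age (30–80) without
truncation.

## Gail relative risk

The parsimonious Gail model uses five clinical covariates: age at menarche
(≥14 / 12–13 / <12), age at first live birth (<20 / 20–24 / 25–29 or
nulliparous / ≥30), number of affected first-degree relatives (0 / 1 / ≥2),
number of breast biopsies (0 / 1 / ≥2, with an age-regime switch at 50),
and an atypical-hyperplasia multiplier applied only when at least one
biopsy was taken (attenuation 0.93 for benign pathology, amplification 1.82
for atypical hyperplasia, 1.0 when unknown). The log relative risk is the
usual linear combination with a first-birth × relatives interaction.
Coefficients are data, not code: they ship as a versioned JSON fixture with
its SHA-256 recorded at load, transcribed from the published model; the
same covariate coefficients are applied to both populations (with
population-specific `1−AR` and rate tables), since population-specific
coefficient tables are not printed in the literature this package tracks.
Users can pass their own table per population.

Ancestry maps to a rate-table population (European → White, Asian →
Chinese) as a configurable default.

### Missing data

Unknown is an explicit categorical level, never an empty cell after
parsing. The primary policy recodes every unknown Gail covariate to the
reference (lowest-risk) category, so an all-unknown subject has rr = 1; the
sensitivity policy recodes to the highest-risk category of each of the four
recodeable variables (menarche → <12, first birth → ≥30 by coefficient
argmax, relatives → ≥2, biopsies → ≥2). Atypical hyperplasia is not
recoded: its unknown level already carries the no-effect multiplier 1.0.
No imputation model is fitted — with a covariate ~95–100% missing, imputed
values would reflect model assumptions rather than data.

Study-level exclusion drops a (study × disease-status) cell when at least
two of the three core covariates (menarche, first birth, family history)
are unknown for ≥50% of the cell (boundary inclusive). Only the `unknown`
level counts as missing; a structurally absent column parses to unknown and
is then indistinguishable, which the provenance log notes. Individual
exclusion keeps ages 30–80, where this class of model is valid.

## PRS

Raw scores are weighted sums of effect-allele dosages (sum-score
convention). Dosage rows are matched to weight variants by id; swapped
effect/other alleles flip the dose to `2 − dose`; missing entries are
mean-imputed from the observed dosages of that variant (2 × effect-allele
frequency), matching standard scoring tools; strand-ambiguous variants
(A/T, C/G) are kept by default and reported, droppable by flag.

Scores are standardized with ancestry-specific control means and SDs (a
per-study option exists), and the percentile is the standard normal CDF of
the z-score. The relative risk of a score is the theoretical odds ratio
against the 40–60th percentile band, treated as the general population:

    rr(z) = exp(β·z) / c,
    c = exp(β²/2)·[Φ(Φ⁻¹(0.6) − β) − Φ(Φ⁻¹(0.4) − β)] / 0.2,

with β the log odds ratio per SD — a configuration parameter defaulting to
ln(1.61), transcribed from the 313-variant score's development publication.

For absolute risk, the banded incidence `h1` is divided by
`m = E[rr(Z)] = exp(β²/2)/c` (Z standard normal) before applying `rr(z)`,
so the population-average incidence hazard reproduces the rate table
exactly. The alternative reading — the middle quintile itself carries the
population incidence — is selectable (`baseline="mid-quintile"`). Note the
conservation is exact on the hazard scale; on the five-year-risk scale the
cohort average differs from the unstratified projection by a small Jensen
gap (the risk formula is concave in `rr`; about −0.6% relative at β =
ln 1.6 with h1 = 0.01, h2 = 0.005), which the tests quantify.

## Evaluation

Odds ratios per unit of continuous five-year risk come from ML logistic
regression with Wald 95% CIs. The default risk unit is one percentage point
of five-year absolute risk (`--risk-unit per-sd` is available; the OR
scale of published consortium tables is convention-dependent, so both are
exposed). AUCs use the Mann-Whitney rank estimator with ties counted ½ and
a DeLong-type placement variance for the CI; the estimator is checked
against an O(n²) pairwise oracle. Age interactions are Wald tests of the
score × age (continuous) coefficient in a separate model. Perfect
separation, constant predictors, and rank-deficient joint fits are flagged
explicitly rather than reported as silent coefficients.

The driver analysis enumerates all 31 non-empty subsets of the five Gail
factors, forces covariates outside the subset to missing (hence reference,
under the baseline policy), rescores the cohort, and reports the AUC per
subset. A subset whose factors are all missing in a stratum yields a
constant score; with the tie convention its AUC is exactly ½ only when the
stratum is also age-homogeneous, because the five-year risk retains its age
dependence even at rr = 1.

## Overlap and enrichment

High-risk flags are boundary-inclusive (`ar5 ≥ t`, so a quoted threshold
like 1.4% flags a subject at exactly 1.4%); the FH flag is threshold-free
(≥1 affected first-degree relative; unknown counts as none). Thresholds
sweep 0.5–2.5% in 0.1-percentage-point steps by default, the granularity
at which such thresholds are commonly quoted. For each threshold the 8
membership patterns over {PRS, Gail, FH} are counted; `unique` fractions
are subjects flagged by exactly one method. The enrichment of a predictor
is (fraction of cases flagged) / (fraction of controls flagged); the
minimal threshold reaching a target ratio (default 2.0) is searched on the
grid. A composition-based alternative (case:control ratio within the
flagged set, normalized by the stratum's base ratio) is available behind
`definition="composition"`. Zero flagged controls yield +∞ with counts
kept for context; infinite ratios do not satisfy the threshold search.

## Calibration (model-based ROC)

In a case-control sample the event fraction does not estimate population
prevalence, so decile-based goodness-of-fit tests are not valid without
design adjustment. Instead the package compares the empirical ROC with the
model-based ROC — the ROC the predicted risks π would generate if they
were perfectly calibrated: sweeping a cut c over distinct values,
TPR(c) = Σ_{π≥c} π / Σπ and FPR(c) = Σ_{π≥c} (1−π) / Σ(1−π). Three tests
are reported:

* **mean calibration** — normal test of Σy against Σπ with variance
  Σπ(1−π);
* **ROC equality** — sup vertical distance between the curves on a
  201-point FPR grid, null distribution by parametric bootstrap that
  regenerates outcomes as independent Bernoulli(π);
* **unified** — Tippett-style combination of the two component statistics
  through their bootstrap null ECDFs.

Bootstrap seeds are fixed and recorded in the output, as are the statistic
definitions. Monte-Carlo checks show all three hold a ≈5% level under the
null and the mean test has power ≥0.95 against a 0.5× risk-scaling
distortion at n = 5000. Because the tests run on the case-control sample
as supplied, rejections speak to calibration relative to the sample's case
mix; predicted risks must be re-based to population prevalence before any
population-level calibration claim. A decile table (equal-count bins,
Wilson binomial CIs) is provided for plotting.

## Synthetic cohorts

The generator reproduces the structure of the consortium cohort this
analysis was designed for, from a packaged characteristics table: six
(ancestry × status) cells at the published sizes (68,540 / 83,685 / 9,624
European controls / invasive / DCIS; 8,347 / 9,222 / 980 Asian), ages
drawn from normals matched to the published medians/IQRs and truncated to
[30, 80], covariate categories (including `unknown`) at the published
per-cell frequencies — which already encode the case-control family-history
enrichment (14% vs 9% European, 10% vs 6% Asian) and the near-total
missingness of biopsy data (94–100%) — and a raw PRS that is normal with
the published control location/scale, shifted in cases by `prs_beta`
standard deviations (default ln 1.61). The shift-by-β rule is the
liability-logit approximation: it makes the per-SD log odds in the
case-control sample exactly β, giving closed-form targets
(e.g. binormal AUC Φ(β/√2)).

Dosage panels draw Hardy-Weinberg genotypes at uniform(0.05, 0.95)
frequencies with normal weights; a final continuous-dosage adjustment
variant (`rsADJUST`, weight 1) absorbs the residual so the weighted sum
reproduces each subject's assigned raw score exactly — synthetic plumbing
for end-to-end scoring tests, not a genotype model. Extra missingness is
MCAR by default with a case-enriched (MNAR) multiplier to exercise the
sensitivity-analysis direction. A separate helper emits
(true risk, predicted risk, Bernoulli outcome) triples with optional scale
or logit-shift distortions for calibration power studies.

The generator does **not** simulate linkage disequilibrium, study-level
heterogeneity, covariate correlations, or informative control sampling.
Green tests on these cohorts establish that the machinery is correct under
the stated data-generating process; they do not validate the clinical
models on real consortium data.

## Problem sizes and determinism

The default test and acceptance runs use scaled-down cohorts (1–10% of the
published cell sizes, chosen so the full suite completes in minutes on one
CPU while keeping every stratum populated); Monte-Carlo operating
characteristics use 500–1000 replicates at n = 2000–5000 and calibration
bootstraps of 200–500 resamples. All randomness flows through
`numpy.random.default_rng` seeds that are fixed in configuration and
recorded in outputs; identical configuration and seed reproduce reports
byte-for-byte (modulo the echoed output path).

## Known limitations

* Coefficients, rate tables and β are research transcriptions, not
  authoritative clinical constants; substitute validated tables before any
  clinical use.
* The same Gail covariate coefficients are applied to both populations.
* Calibration conclusions are case-mix-relative (see above).
* Country-level stratification within ancestry, protein-truncating-variant
  descriptives, and ancestry-specific PRS development are out of scope.
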