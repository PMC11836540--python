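# Methods

`lingcast` projects the number of first-language speakers of small
languages — populations observed only through repeated, noisy, privacy-
perturbed census counts — from a 2001 baseline to 2101, and quantifies the
risk that a language becomes dormant (zero living first-language speakers).
This note documents the model, its assumptions, the numerical choices, and
what the synthetic-data experiments do and do not establish.

## Model overview

The pipeline has four stages.

1. **Cohort recasting.** A count observed at census year *t* for the
   five-year age group [a, a+4] belongs to the birth cohort
   [t−a−4, t−a]. Counts for the cohorts 1917–1921 … 1997–2001 — the 17
   cohorts observable at every census 2001–2021 — are made comparable at
   2001 by survivorship inversion, N₂₀₀₁ = N_t / (1 − M), where M is the
   cumulative probability of dying between 2001 and *t*, accumulated over
   five-year steps as 1 − Π(1 − q(age, period)) with the cohort's age-group
   label taken at each step's start. The same machinery run backwards
   (dividing by survival over [year, 2001]) recasts a 2001 population into
   1981–1996. Forward and backward recasts are exact inverses; the suite
   checks the round trip to 1e−9. Migration and language attrition are
   assumed negligible (closed population).

   One corner is forced by the age ladder: cohort 1917–1921 is aged
   100–104 at the 2021 census and falls into the open-ended "100+"
   category, which mixes cohorts and cannot be assigned; that cohort
   therefore carries four estimates instead of five, and the 2021 census
   total imputes the missing cell with the cohort's cross-census mean so
   the five totals stay comparable.

2. **Quality screening.** Because some censuses under-enumerate specific
   communities, recast estimates are screened before fitting. Each census
   total is compared with the mean of the other censuses' totals,
   studentized by their standard deviation with the prediction factor
   √(1 + 1/m), and referred to a t distribution with m−1 degrees of
   freedom; totals with p < 0.001 are dropped from the total-size fit.
   Age cells are screened the same way within each cohort row (p < 0.01)
   after a robust, median-based column normalisation that removes
   whole-census coverage shifts without letting a single contaminated cell
   drag its column. The studentizing scale is floored at the standard
   deviation that base-5 random rounding alone induces (2 per cell,
   √17·2 ≈ 8.25 for totals), so the disclosure-control mechanism can never
   trigger an exclusion; without that floor, tiny languages whose cohort
   rows look like {0, 0, 5, 0, 0} lose their only informative observation
   and downstream transmission estimates inherit a visible bias.
   The leave-one-out form matters: with five observations, a pooled
   z-statistic is bounded by (n−1)/√n ≈ 1.79 and could never reach the
   0.001 threshold, however gross the outlier. Exclusions never reduce a
   language below the three censuses the baseline fit needs.

3. **Probabilistic baseline (2001).** The model separates total-size error
   from age-composition error. The (screened) recast totals define a
   t-distribution with location µ (mean), scale τ (standard error of the
   mean, sd/√n) and n−1 degrees of freedom. Each cohort gets a count
   distribution fitted by moments: negative binomial with mean µ_c and
   quadratic mean–variance relation σ² = φµ_c² (φ = σ²/µ_c², the
   overdispersion), falling back to Poisson when the sample variance does
   not exceed the mean and to a point mass at zero for empty cohorts. A
   baseline draw takes one total T from the t-distribution (truncated at
   zero and rounded — populations are non-negative integers; truncation is
   only active for languages whose total is within a few τ of zero) and 17
   cohort counts, then rescales the cohort vector to sum exactly to T by
   largest-remainder rounding, which preserves the sum without systematic
   bias. If every cohort draw is zero while T > 0, T is spread
   proportionally to the cohort means.

4. **Transmission trends and projection.** From each baseline draw the
   mean number of child speakers per adult speaker is computed with the
   xTFR estimator, xTFR = (10.65 − 12.55·π₂₅₋₃₄)·C/W, where C is the count
   at ages 0–4, W at 15–49 and π₂₅₋₃₄ the 25–34 share of W. Applied to
   speakers of both genders, replacement sits near one child per adult
   speaker. Five historical values (1981–2001, the first four via backward
   recasting) are fitted with one of two forms: declining series (negative
   least-squares slope) get a log-linear model, ln(xTFR) ~ year;
   non-declining series get xTFR ~ ln(year) constrained through an anchor
   at 2096 equal to the 1981–2001 mean, which keeps growth extrapolations
   bounded. The `freeze` scenario evaluates the fitted curve to 2046 and
   holds it constant to 2096; `unlimited` evaluates it throughout. Values
   are floored at zero; before taking logs, values are floored at
   ε = 0.005 (half the smallest magnitude the statistic is meaningfully
   reported at — the fitted slope is insensitive to ε within a factor of a
   few because floored values are near-zero in both response and weight).
   Calendar years are centred at 2001 in the log-linear fit for numerical
   hygiene; the log-year form uses raw calendar years.

   The projector is an individual-based cohort-component model in
   five-year steps, 2001–2101. Survivors of age group a are
   Binomial(count, 1 − q(a, period)) — the exact aggregate of independent
   per-individual Bernoulli trials — and move up one group; q(95–99) is
   forced to 1, enforcing a maximum age at death of 100. Expected births
   are Σ_a count(a)·xTFR_t·w_t(a) over reproductive groups, realised as one
   Poisson draw (individual parities are not modelled), and entrants to
   0–4 are the births thinned by the infant survival probability
   (1 − q(0–4))^½, a half-interval power under constant hazard within the
   interval. Births use the start-of-period population — the simplest
   consistent discretization. The 2001–2006 step uses the draw's observed
   2001 xTFR; projected values serve 2006 onward.

   Birth-allocation weights come from a log-normal age pattern: for the
   2001 and 2100 reference years the age-specific fertility rates are
   normalised over the seven group midpoints (17.5 … 47.5) and a
   log-normal density (location m, scale s on log-age) is least-squares
   fitted to the profile; (m, s) are linearly interpolated in calendar
   year (one-year extrapolation to 2101), and the per-period weights are
   the density at the midpoints renormalised to sum to one.

Each ensemble replicate (default 3000 per language) redraws the baseline,
the historical xTFR series, the trend fit and the stochastic trajectory.
Replicate substreams are spawned from the master seed with numpy's
`SeedSequence`, so any replicate is reproducible in isolation and whole
runs are bit-reproducible from (inputs, config, seed).

## Summaries

Medians and 0.1/0.9 quantiles (80% projection intervals) are reported per
year, in total and by age group, using the inverse-empirical-CDF ("lower")
quantile convention — pinned because counts are small integers and the
convention is visible in the output. Dormancy risk is the percent of
replicates with zero speakers in a band (all ages, under 50, under 15) at
a year, with the first years at which risks reach 10% and 50%. The
all-ages and under-50 bands are absorbing (no speakers under 50 ⇒ no
reproductive-age speakers ⇒ no future births), so their risks must be
non-decreasing in time and the code asserts this — a violation would be an
engine bug. The under-15 band is *not* absorbing (speakers aged 15–49 can
produce new child speakers after a childless spell), so its risk is
reported unadjusted and no monotonicity is asserted.

Hindcast validation compares, for each census year and modelled age group,
the observed count with the replicate [q10, q90] band and reports the
covered share, overall and stratified by year and age.

## Synthetic data

The generator produces exactly what the pipeline assumes: a closed
population whose true age structure evolves by a deterministic expectation
recursion under known mortality and a known transmission trajectory,
observed by censuses 2001–2021 with negative-binomial noise
(variance = φ·mean², matching the estimator's quadratic assumption; a
Poisson switch exists for misspecification experiments), optional
whole-census undercount factors, and unbiased base-5 random rounding
(round up with probability remainder/5). Post-2001 true transmission
follows the pipeline's own freeze-form trend fitted to the noise-free
1981–2001 series, so the synthetic world is exactly the model's assumed
world. The expectation recursion doubles as the independent oracle for the
stochastic projector.

Four named presets span the qualitative regimes seen in Canadian census
counts of Indigenous first languages: `large_growing` (~2 500 speakers in
1981, young pyramid, transmission rising 1.5 → 1.9), `large_declining`
(~45 000, transmission decaying exponentially 1.30 → 0.85),
`small_declining` (~600, collapsed transmission 0.40 → 0.01) and
`tiny_near_dormant` (~120, old pyramid, 0.30 → 0.04). Census noise is
φ = 0.005 (a ~7% coefficient of variation, a plausible magnitude for
small-area census counts of minority-language speakers). A 27-language
bundle extends these with log-uniform sizes (60–60 000) and varied trends.
The shipped life table and fertility schedule are synthetic, WPP-like
fixtures: life expectancy rises from ~69 years (1981) to ~86.7 (2096)
under a Siler-style hazard solved per period against a one-year-grid life
table (so the abridged five-year closure is an honest approximation,
checked to 0.5 years), and the fertility profiles have TFR ≈ 3.4 in 2001
and ≈ 1.8 in 2100 with postponement.

What passing tests on this synthetic world show: the estimators are
consistent and approximately unbiased under the model's own assumptions
(transmission recovered with mean absolute bias ≤ 0.035; the true total
covered by the 80% baseline band 77–88% of the time), the stochastic
engine agrees with its expectation recursion, and the whole chain is
reproducible. What they do not show: robustness to real-census features
the generator omits — correlated under-enumeration across adjacent
censuses, weighting/imputation artefacts, migration, and language shift.

## Calibration of the projection intervals

A self-consistency experiment generates the four-preset bundle, runs the
pipeline at 3000 replicates, and measures how often the synthetic observed
cells fall inside the per-cell 80% bands (this is what
`scripts/acceptance.py` recomputes). Pooled over all year × age cells the
coverage comes out near 86%, not 80%, and this is a property of the
validation design rather than a miscalibration:

* the comparison is in-sample — the observed censuses are the same five
  observations the baseline was fitted to. The expected in-sample coverage
  of a mean ± 1.2816·s band built from n = 5 observations is 82.7% even in
  the ideal continuous-normal case (a fresh observation would be covered
  only ~70% of the time);
* integer counts make lower-quantile bands over-cover: a band on a count
  distribution with mean of a few speakers covers ≥ 80% by construction,
  often ~90–95%; cells that are structurally zero on both sides count as
  covered;
* plug-in variance estimates from five observations (a χ²₄ scale) push the
  other way for large languages, whose per-language coverage sits near
  75%.

Measured nontrivial-cell coverage (~83%) matches the 82.7% in-sample
benchmark almost exactly. On real data, where census dispersion exceeds
the fitted model's, the same validation is expected to come out *below*
nominal instead.

## Numerical and degenerate-input choices

* Quantiles: `numpy` `inverted_cdf`. Ties in largest-remainder rounding
  break by larger fractional part, then lower index (deterministic).
* Trend tie-break: a least-squares slope of exactly zero takes the
  non-decreasing (mean-anchored, bounded) branch. All-zero series project
  identically zero.
* xTFR with W = 0 raises in the scalar API; the series/ensemble path
  substitutes 0 with a warning (dormant-population convention).
* A fertility pattern with s → 0 allocates all births to the group whose
  midpoint is nearest exp(m).
* Monte-Carlo oracle comparisons use a Poisson variance floor on the
  standard error, since cells whose expected count is a small fraction of
  a speaker can be legitimately all-zero in a finite sample.

## Problem sizes in the shipped suite

The test suite runs the calibration experiment at the full 3000 replicates
for the four-language bundle, parameter recovery at 200 regenerated
bundles per preset, and oracle comparisons at 1200 replicates per preset;
the whole suite completes in a few minutes on one CPU. Larger bundles (the
27-language structural check) run at fitting level only.

## Known limitations

* Single well-mixed population per language: no geography, no migration,
  no acquisition of the language by new speakers, no two-sex structure.
* Transmission enters only through xTFR; the estimator's own demographic
  approximation (exact only for stable-ish age schedules) is not corrected
  — parameter-recovery targets are therefore defined as the xTFR
  functional evaluated on the true population, not the generative input.
* Baseline uncertainty ignores covariance between cohorts beyond the
  shared total.
* The under-50 absorbing argument assumes births only from ages 15–49,
  which the weight construction guarantees.
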