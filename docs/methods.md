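# Methods

`pnnskit` implements the analysis chain used to relate adherence to the
French food-based dietary guidelines (FBDGs) to adult weight change:
repeated 24-hour dietary records are reduced to a usual diet, scored against
the 2017 (PNNS-GS2, with its simplified variant sPNNS-GS2) and 2001
(mPNNS-GS1, physical activity removed) guideline indices plus AHEI-2010,
and the standardized scores are related to overweight/obesity incidence
(left-truncated Cox models on the age timescale) and to log-BMI
trajectories (a multilevel model with serially correlated residuals).
Because the motivating cohort data are access-restricted, the package ships
a first-class synthetic-cohort generator with known ground truth; every
stage is exercised end to end against it.

## Usual diet and under-reporting screen

A participant's usual diet is a weighted mean of their record days:
weekday records receive weight 5/7 and weekend records 2/7, matching the
sampling design of two weekdays plus one weekend day per record triplet.
If one stratum is empty the unweighted mean is used and a warning logged,
rather than discarding the participant.

Energy intake without alcohol (EIWA) is total energy minus 7 kcal per gram
of ethanol, floored at zero. Gram intakes convert to servings with
configurable serving sizes (defaults: fruit/vegetable 80 g, dried fruit
30 g, nuts handful 30 g, legumes 60 g, grains 50 g, dairy 150 g
milk-equivalent, fish and meat 100 g, beverage glass 240 ml). Juice and
dried-fruit servings are each capped at 1/day *after* averaging records —
whether the capping should precede averaging is not decidable from the
source material; capping the usual diet is the documented choice here.

Implausibly low reporting is flagged by the Goldberg cut-off applied to the
ratio of reported energy intake to the Schofield (weight-only) basal
metabolic rate: the lower limit is `PAL * exp(-2 s/100)` with
`s = sqrt(CV_wEI^2/d + CV_wB^2 + CV_tP^2)`, `d` the number of record days,
and conventional parameter values PAL = 1.55, CV_wEI = 23%, CV_wB = 8.5%,
CV_tP = 15%. With six record days the cut-off is about 1.05. All parameters
are configurable (`BlackParams`). Flagging is strict (`ratio < cutoff`).

## Scoring engines

Every threshold of both guideline indices lives in
`src/pnnskit/data/score_definitions.yaml`; the engine knows only how to
evaluate bands, so the entire table is data. Bands carry explicit
inclusive/exclusive endpoints and are validated at load time to tile their
domain with no gaps or overlaps.

* **PNNS-GS2** — 13 components (6 adequacy, 7 moderation), total
  `sum_c w_c (band points + sub-item points)` with the printed weights
  (1-3). Sub-items: organic bonuses (0.5 / 0.25 / 0 by frequency; the
  rice-pasta and legume bonuses are nullified when the food was never
  reported consumed), the fatty-fish item, the vegetal and ALA/olive fat
  ratios, and the white-ham bonus which only applies when processed meat
  exceeds 150 g/week. The weighted-sum aggregation is isolated in one place
  so an alternative rule can be swapped in without touching band logic.
* **sPNNS-GS2** — the same weighted engine restricted to each component's
  principal recommendation (no sub-items).
* **mPNNS-GS1** — 12 components, unweighted. The printed added-fat row is
  encoded as two components (energy-share limit; vegetal-fat ratio), which
  reproduces the stated count of 12. The alcohol component gives abstainers
  and irregular consumers (less than once a week) 1 point regardless of
  amount; "regular" is derived from the records as drinking on at least
  1/7 of days. Dairy bands are age-conditional (55-year threshold), and the
  beverage rule combines water (>= 1 l/day) with soda (<= 250 ml/day).
* **AHEI-2010** — the trans-fat component is unavailable from food-group
  records, so the index is the 10 remaining components (0-10 each, total
  0-100), linearly interpolated between configurable 0- and 10-point
  cutoffs; sodium uses fixed g/day cutoffs standing in for cohort deciles,
  and the alcohol component is the usual non-monotone piecewise rule with a
  2.5-point floor for non-drinkers. Long-chain omega-3 and PUFA inputs are
  approximated from fatty-fish grams (15 mg EPA+DHA per g) and from the
  vegetal share of added-fat energy; these proxies are configurable serving
  constants and are documented as approximations.

Two deliberately literal encodings: the fat-ratio rows score "ratio <= 50%
-> 1 point" on the vegetal-fat ratio exactly as printed, and the 2017
alcohol bands use the printed g/day limits (0; (0-100]; (100-200]; >200)
although the magnitudes look weekly-scaled. Both are data-file entries, not
code, so a corrected table is a one-line edit.

All four totals are standardized by dividing by the sample standard
deviation (n-1 denominator, no centering), the form required for the
one-model score comparisons.

## Cohort preparation

Baseline is the midpoint of the first and last record dates (the middle of
the exposure window). The selection cascade retains participants with at
least three records within two years of inclusion, anthropometric
follow-up, and complete covariates; under-reporter exclusion and the
sensitivity rules (clinical-condition flags, BMI below the working sample's
first percentile — computed before outcome-specific exclusions) are
switchable. The exclusion log partitions the input exactly.

Overweight/obesity events (BMI >= 25 / 30, morbid obesity 40 via the same
configurable threshold) are timed at the midpoint between the first
questionnaire at or above the threshold and the previous one; when the
first post-baseline measure already crosses, baseline acts as the previous
measure. Follow-up is left-truncated at the baseline age and censored at
the last questionnaire. Participants at or above the threshold at baseline
are excluded from that analysis.

Quintiles are sex-specific by default (a flag switches to pooled), with
stable rank-based ties so group sizes differ by at most one. Descriptive
association tests dispatch on variable type: chi-squared (unordered),
Cochran-Armitage trend (binary; hand-coded, no installed implementation
exists), Spearman (ordered) and a linear-contrast slope on the quintile
index (numeric). Food-group intakes can be energy-adjusted by the residual
method within sex, preserving the grand mean.

## Survival models

`fit_cox_left_truncated` delegates to lifelines' Cox fitter with delayed
entry (risk sets `entry < t <= exit`), Efron tie handling, and a Newton
convergence tolerance of 1e-9 so that estimates agree with a brute-force
partial-likelihood maximizer to 1e-4 on small data. Continuous adjustment
covariates can be expanded on a restricted cubic spline basis with three
knots at their 10th/50th/90th percentiles (z-scaled first for
conditioning); splines are never applied to the exposure score. The
exposure enters as sex-specific quintile indicators (Q1 reference), per
point, or per SD; the quintile trend test assigns each quintile its median
score and re-enters it continuously.

Proportional hazards are checked with Schoenfeld residuals computed
honouring left truncation (lifelines cannot produce them with delayed
entry) and the Grambsch-Therneau statistics on rank-transformed event
times: per-covariate `d (Vz)_k^2 / (V_kk * sum g^2)` and global
`z'Vz * d / sum g^2`.

The one-model score comparison fits both standardized scores in a single
model and tests coefficient equality by Wald:
`(b_a - b_b)^2 / (V_aa + V_bb - 2 V_ab)` on 1 df.

In the pipeline, factor levels with fewer than 10 participants are pooled
before the Cox design, and the quintile exposure form is skipped (with a
recorded note) when some quintile has zero events — small-sample guards
that do not alter well-populated analyses.

## Longitudinal model

The model is `log BMI_it = x_it' beta + b0_i + b1_i t + e_it` with an
unstructured 2x2 random-effect covariance and continuous-time first-order
autocorrelated residuals, `corr(e_is, e_it) = rho^|t-s|` (the "spatial
power" structure; compound-symmetry and independent alternatives are
available and comparable by AIC). No installed mixed-model implementation
combines random slopes with residual autocorrelation, so estimation is
written here: the marginal covariance is assembled per participant,
participants with equal numbers of measures are batched into stacked
Cholesky factorizations, the residual variance is profiled out, and the
restricted likelihood is maximized by L-BFGS-B over four transformed
parameters (log-Cholesky of the relative random-effect covariance, logit
autocorrelation) with tolerance 1e-8, at most 500 iterations, box bounds
that keep the covariance assembly well conditioned, and a large finite
penalty (never infinity) on degenerate evaluations so numerical gradients
stay usable; a warm start that ends in a failed or degenerate state
triggers a cold restart from the default initial values. A
maximum-likelihood variant is available for nested-model comparisons,
since restricted likelihoods are not comparable across fixed-effect sets.
In the rho -> 0 limit the fits agree with statsmodels MixedLM (which, on
the same data, requires a non-default optimizer to converge and then
reaches a slightly worse restricted-likelihood optimum).

Fixed effects are the standardized score, time since baseline, their
interaction, the adjustment set (m0: sex, age, log EIWA, number of records;
m1: plus height, month of inclusion, physical activity, occupation,
smoking, education, income, cohabiting) and, by default, the score x sex,
time x sex and score x time x sex interactions; the exact interaction set
is switchable because it is not fully determined by the source analysis.
Because the outcome is log-transformed, a shift of `dS` score SDs sustained
over `t` years multiplies BMI by
`exp(dS*b_score + t*b_time + t*dS*b_interaction)` (`bmi_multiplier`).
The one-model comparison includes both scores and both score x time terms
and reports two Wald equality tests (baseline and slope).

## Synthetic cohort

The generator emulates the study inputs with one global seed split into
per-stream substreams (participants, records, organic, anthropometrics).
Defaults mirror the emulated cohort where stated: 76.1% women, age 47.1
(SD 14.1) truncated at 18, six years of follow-up, records in
2-weekday/1-weekend triplets within the first two years (default 6 per
participant), organic frequencies categorical over three levels, and
food-group means near the published consumption table (fruits 212 g/day,
vegetables 228 g/day, ...). A latent standard-normal "diet quality" trait
scales healthy groups up and discouraged groups down (0.35 log-units per
SD), producing realistic correlated intake profiles and hence a spread of
guideline scores. Energy is anchored to the Schofield BMR: ordinary
reporters draw EI:BMR from N(1.5, 0.18) truncated at 1.2, while a planted
fraction of under-reporters draws 0.60-0.85 times their Goldberg cut-off,
so the screen fires on exactly the planted group up to sampling noise.
Ethanol is capped at 80% of the day's energy so EIWA stays positive.

Log-BMI trajectories invert the longitudinal model: participant anchors
(lognormal around BMI 23.3), the standardized PNNS-GS2 computed by the
package's own intake + scoring pipeline, generating coefficients
`beta_score = -0.040`, `beta_time = 0.0027`,
`beta_interaction = -0.0008` (chosen to match the magnitudes the method is
meant to detect), random intercept/slope SDs 0.15 and 0.004, residual SD
0.02 with rho = 0.5, and measures every 0.5 years (with 0.08-year jitter)
over six years, i.e. roughly 12 weight measurements per participant.
The questionnaire interval and jitter, and a dropout process (none by
default), are config knobs the source does not pin down. Threshold
crossings are not simulated as hazards; they emerge from trajectories, so
the survival stage sees the same outcome definition as the real analysis.
A separate piecewise-exponential generator with a known per-SD log hazard
ratio (constant baseline hazard on the age timescale, uniform
administrative censoring) serves the Cox oracle and calibration tests.

What the generator does *not* emulate: seasonality of diet, item-level
food composition, measurement error in self-reported height, informative
dropout, and real covariate-diet confounding beyond the latent-trait
gradient. Passing tests therefore demonstrate correctness of the
computational chain and statistical calibration under the stated model,
not robustness to those real-data features.

## Verification scales and numerical choices

Test problem sizes are chosen to keep the default suite within a routine
CI run: scoring oracles are exact and instantaneous; the Cox brute-force
oracle uses datasets of up to six subjects; Wald-test calibration uses
null simulations of 2,000 participants per model family (500 for the Cox
family, 1,000 for the mixed model, whose rejection rate sits a little
above nominal and therefore needs the smaller Monte-Carlo error to be
located; the band 3.5-6.5% at alpha = 0.05 is about +/-2 binomial SDs);
parameter recovery uses 100 replicates of 5,000 participants, with the
score distribution taken from one full dietary-pipeline run and the
score-to-participant assignment re-randomized each replicate (scores and
anchors are exchangeable, so this preserves unbiasedness while avoiding
the cost of regenerating diets). Warm starts carry variance-component
estimates between successive replicate fits; they change only iteration
counts, not optima.

Degenerate-input conventions: empty record sets, non-positive EIWA,
constant covariates, zero-SD score panels, all-equal quintile scores and
baseline-exceeding thresholds all raise errors rather than guessing;
white-ham ratio with zero processed meat is 0; ethanol energy above total
energy floors EIWA at 0 with a warning.

## Known limitations

* The GS2 weighted-sum aggregation and the printed GS2 alcohol band units
  follow the printed table; both are flagged in the definitions file and
  trivially editable if the underlying construction differs.
* AHEI sodium uses fixed cutoffs, not within-sample deciles.
* The Cox stage fits each threshold independently; no shared frailty or
  competing risks.
* REML standard errors ignore variance-parameter uncertainty (the usual
  Wald approximation); with thousands of participants this is negligible,
  as the calibration suite verifies.
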