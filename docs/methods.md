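# Methods

`trialdistill` implements a three-stage re-analysis ("distillation") of a
two-arm randomized trial whose intervention arm showed variable engagement —
the situation of care-management trials such as the Health Care Hotspotting
(Camden Core Model) evaluation, whose structure the synthetic generator
emulates.  An intent-to-treat (ITT) contrast estimates the effect of the
*offer* of treatment; when many treatment-arm enrollees receive little or no
intervention dose, that estimate is diluted relative to the effect of
delivered treatment.  Distillation narrows the analysis population — in both
arms, using only prerandomization information — to subsets increasingly
enriched with likely engagers, trading sample size for a contrast closer to
the delivered-treatment effect while preserving randomization.

## Stage 1: engaged participation

A treatment-arm enrollee is an **engaged participant** when at least
`criteria_required` (default 2) of three criteria hold:

1. *early dose* — ≥ `min_hours_early` (3 h) of contact time within the first
   `early_window_days` (14 d) of enrollment;
2. *weekly contact* — contact in ≥ `min_weeks_with_contact` (4) of the first
   `contact_window_weeks` (6) weeks;
3. *retention* — retained `retention_days_required` (60) days, or formal
   graduation on or before that day.

Interpretation choices the rule leaves open: weeks are 7-day blocks from
enrollment (`[7w, 7w+7)`), which is calendar-agnostic and deterministic;
"graduated within that timeframe" means `graduation_day ≤ 60`; zero-duration
contacts count toward the weekly criterion but not the hours criterion; only
completed contacts are counted.  Engagement is antitone in every threshold
(tightening the rule can only demote), a property the tests check by random
perturbation.  A sensitivity runner re-executes the whole pipeline over a
grid of threshold settings.

The engagement label is then modeled from **prerandomization covariates
only** with a gradient-boosted classifier (scikit-learn's
`GradientBoostingClassifier`): depth-2 trees (2-way covariate interactions),
learning rate 0.001, up to 10,000 trees, with the tree count self-selected at
the optimum of 8-fold cross-validated AUC (stratified folds, seeded; ties go
to the smallest count).  Continuous covariates enter raw — trees are
scale-invariant — and categoricals are one-hot encoded with the level set
taken from the full two-arm table, so levels absent from the training arm
still score (as all-zero indicator columns).  Categorical levels with fewer
than `rare_level_min_count` (5) members are first merged into the retained
level with the highest treatment-arm engaged rate (alphabetical tie-break).
Relative influences are the ensemble's impurity-based importances aggregated
over each covariate's dummy columns, normalized to 100%.

The classifier sits behind a fit/predict/influence contract and two
configurations are shipped: the reference profile above (single analyses),
and a scaled-down replicate profile (learning rate 0.08, ≤ 200 trees, 3-fold
CV, AUC evaluated every 10 stages) used for the simulation studies, where
hundreds of pipeline replicates are fit per study.  On the default synthetic
scenario the two profiles rank participants near-identically (held-out AUC
differences within fold noise); the replicate profile simply trades the
per-tree CV resolution for speed.

**Assumption surfaced, not assumed.**  The method helps only insofar as the
estimated engagement probability tracks the person-level treatment effect.
On synthetic runs the pipeline reports this association directly
(`diagnostics.json`: Spearman correlation between score and latent
propensity, AUC of score against the counterfactual would-engage indicator).

## Stage 2: distillation

All participants in both arms are ranked by the fitted score — a fixed
function of prerandomization covariates, applied identically to both arms, so
arm membership within any score-defined subset remains randomized
("arm-blindness").  The top-f% subset keeps the `floor(f × N)` highest-ranked
participants (this convention reproduces the published 782 → 469 → 156
sizes; ceiling would give 470/157).  Score ties break by ascending
participant id — deterministic and blind to arm and outcome.  Deciles use cut
points `floor(k·N/10)` on the same ranking, so the union of the top k deciles
equals the corresponding top-f% subset exactly.  The stage-1 model is fit
once and frozen; no subset triggers refitting.

## Stage 3: effect estimation

Within each subset, readmission indicators are modeled with binomial-family
(logistic) GLMs and counts with Poisson-family GLMs (statsmodels), each
unadjusted (intercept + treatment indicator) and adjusted (+ baseline
covariates; the default list is the full stage-1 covariate set, shared across
horizons).  Follow-up windows are fixed, so the Poisson models carry no
exposure offset, and no overdispersion correction is applied; a
negative-binomial refit is available as a diagnostic cross-check only.  The
effect measure is `exp(β_treat)` — an OR for rates, an IRR for counts — with
95% Wald CIs `exp(β ± 1.959964·SE)`, SEs from the Fisher information matrix,
and two-tailed Wald p-values (α = .05); the CI excluding 1 is equivalent to
p < .05 by construction.  No multiple-testing adjustment is made across
fractions or horizons; the whole curve is reported and should be read as
such.

Unadjusted estimates have closed forms — OR = (a·d)/(b·c) on the 2×2 table,
IRR = ratio of arm mean counts — implemented independently and used as
oracles: the fitted GLMs must agree to 6 significant digits (the GLMs run
with IRLS tolerance 1e-11 to make that meaningful).  Degenerate subsets
(single-class outcomes, an all-zero arm, separation, constant covariates) are
returned as *flagged* estimates carrying a diagnostic string; the curve never
contains silent NaNs.

Because arm-level summaries pin down everything an intercept-plus-indicator
GLM sees, published results can be reconstructed without microdata: a rate r
and arm size n give `round(r·n)` events, a mean count m gives `round(m·n)`
total events.  The acceptance script reproduces the published full-population
unadjusted ORs (0.85 / 0.87 / 0.93 at 30/90/180 d) and IRRs (0.99 / 0.98 at
90/180 d) this way.  The 30-day IRR is excluded: the ratio of the published
rounded means (0.35/0.38) is 0.921, which rounds to 0.92 — the published 0.93
was evidently computed from unrounded means that summaries alone cannot
recover.

## Synthetic generator

The generator defines the study conditions for all validation.  Defaults:
400 participants per arm; covariate margins matching the emulated trial's
full-population column (mean age 56.6 (SD 12.7), 50.5% female, 29.5%
Hispanic / 54.6% non-Hispanic Black / 15.9% non-Hispanic White plus a ~0.5%
residual category that exercises rare-level recoding, 9.8% homeless, 6.0%
arrested in the prior 6 months, mean 2.7 prior admissions, mean 7.0-day index
stay, and the chronic-condition prevalences of that column); engagement
propensity logistic in the covariates, intercept calibrated by root-finding
so the mean propensity hits `engagement_rate` (default 0.5), with coefficient
signs chosen so distillation shifts characteristics the way the real
re-analysis observed (older, more female/Hispanic, less arrest history and
liver disease, more COPD and kidney disease); readmission counts as Poisson
increments over the 30/90/180-day windows with log-link covariate
heterogeneity, control-arm cumulative means 0.38/0.89/1.48, and a
multiplicative treatment effect of `effect_engaged` (default 0.75) among
would-be engagers and `effect_nonengaged` (default 1.0) otherwise.
Indicators are derived as count ≥ 1, so outcome-consistency invariants hold
by construction.

Engagement logs are minimal-but-sufficient: each criterion is independently
satisfied with probability 0.9 (would-engagers) or 0.1 (non-engagers) and a
contact log realizing the pattern is emitted; under 2-of-3 this yields ~97% /
~3% realized engagement in the two strata.  The generator does **not**
emulate claims data, visit-process dynamics, informative missingness
(missingness is MCAR), overdispersed counts, or correlation structures beyond
the shared covariate effects — so passing tests demonstrate correctness of
the pipeline's logic and calibration under a well-specified Poisson world,
not robustness to real-data pathologies.

A closed-form dilution reference gives the expected ITT contrast: on the
count scale `IRR_ITT = p·e₁ + (1−p)·e₀` for engagement rate p and stratum
effects e₁, e₀; for rates, arm-level event probabilities are Poisson tails
`1 − exp(−λe)` mixed over strata.  These are the oracles for the recovery
study.

## Validation studies and problem sizes

* **Parameter recovery** — 200 replicates at 400/arm, `effect_engaged` 0.6,
  engagement rate 0.5, informative covariates, replicate stage-1 profile:
  the 20%-distilled unadjusted IRR must be closer to 0.6 than the ITT
  estimate in ≥ 90% of replicates.
* **Null calibration** — 200 replicates with no effect in either stratum:
  the share of 95% CIs excluding 1 (both OR and IRR, at 100/60/20%
  distillation) must stay within the 99.9% binomial band around 5%
  (roughly 1–10.5% for 200 trials).
* **Qualitative patterns** — planted scenarios where the generator forces
  them: engagement driven by age alone must produce monotone mean-age shift
  across 100/60/20%; a strong engager-confined effect (0.5 at 2000/arm) must
  produce adjusted-OR point estimates non-increasing beyond 50% distillation
  up to a 0.05 Monte-Carlo step allowance.

Replicate counts and the per-replicate sample size of 400/arm match the
emulated trial's scale; the 2000/arm trend check uses a larger sample so the
curve's shape is dominated by signal rather than subset noise.

## Known limitations

Engagement is labeled from post-randomization logs (within the treatment arm
only, as in the source method); the package cannot explain *why* engagement
varies.  Probability calibration of stage-1 scores is not attempted —
distillation needs only the ranking.  Wald intervals can be anticonservative
in very small, deeply distilled subsets; such cells are flagged rather than
suppressed.  Survival/time-to-event outcomes and cost outcomes are out of
scope.
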