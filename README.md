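# trialdistill

Population-distillation re-analysis of randomized trials with variable
intervention engagement.

## The problem

Care-management and other service-delivery RCTs routinely randomize people to
an *offer* of treatment; many in the treatment arm then engage little or not
at all.  The intent-to-treat (ITT) contrast — everyone as randomized — then
estimates the effect of the offer, not of the delivered intervention, and is
diluted toward the null in proportion to non-engagement.  Per-protocol or
as-treated contrasts fix the dilution but break randomization.

The **distillation method** keeps both.  Its three stages:

1. **Label engagement.**  Treatment-arm enrollees are classified as *engaged
   participants* by a 2-of-3 rule over their contact logs: ≥ 3 intervention
   hours in the first 2 weeks; contact in ≥ 4 of the first 6 weeks; 60-day
   retention or earlier graduation (all thresholds configurable).
2. **Model engagement from prerandomization covariates.**  A gradient-boosted
   classifier (depth-2 trees, learning rate 0.001, ≤ 10,000 trees self-selected
   by 8-fold cross-validated AUC) is fit on the treatment arm and used to score
   *every* participant in both arms.  The score ŝ(x) is a fixed function of
   baseline covariates x, so within any score-defined subset, arm membership is
   still randomized.
3. **Estimate effects in distilled subsets.**  The population is narrowed to
   the top-f% by ŝ (f = 100% … 20%, size ⌊f·N⌋).  Within each subset,
   readmission rates are modeled by logistic regression (effect = odds ratio)
   and readmission counts by Poisson regression (effect = incidence rate
   ratio), unadjusted and covariate-adjusted, with 95% Wald CIs
   exp(β̂ ± 1.96·SE) from the Fisher information.

Because the trial data this method was developed on are not public, the
package ships a synthetic-trial generator emulating that trial's structure
(two arms of ~400, covariate-driven engagement realized only in the treatment
arm, effects confined to would-be engagers, correlated 30/90/180-day
readmission outcomes) plus ground truth, so every stage is testable by
parameter recovery.  See `docs/methods.md` for the full model description.

## Worked example

```python
import trialdistill as td

# a synthetic trial: 400/arm, effect IRR 0.6 confined to would-be engagers
scenario = td.SimulationScenario(seed=3, effect_engaged=0.6)
records, truth = td.simulate_trial(scenario)

labels = td.label_treatment_arm(records)           # stage 1a: 2-of-3 rule
cov = td.covariate_frame(records)
cov, report = td.recode_rare_levels(cov, labels)   # merge sparse levels
treat = [r.participant_id for r in records if r.arm == "treatment"]

from trialdistill.propensity import FAST_STAGE1    # scaled-down boosting profile
model = td.fit_engagement_model(cov.loc[treat], labels, FAST_STAGE1,
                                report, encoding_reference=cov)
scores = td.predict_engagement(model, cov)         # stage 1b: both arms scored

frame = td.analysis_frame(records)
subsets = td.subset_series(scores.to_dict(), [1.0, 0.6, 0.2])
for s in subsets:                                  # stages 2 + 3
    est = td.fit_count_model(s, frame, horizon=180)
    print(f"top {s.fraction:.0%}: n={est.n_used}  "
          f"IRR {est.point:.2f} ({est.ci_low:.2f}-{est.ci_high:.2f})")
```

Output:

```
top 100%: n=800  IRR 0.88 (0.78-1.00)
top 60%: n=480  IRR 0.64 (0.54-0.77)
top 20%: n=160  IRR 0.58 (0.42-0.79)
```

Read: the full-population (ITT) estimate 0.88 is diluted — half the treatment
arm never engaged and carries no effect.  Narrowing to the people most likely
to engage (both arms, by baseline covariates only) moves the estimate toward
the true engager-specific effect of 0.6 and it remains significant despite
the smaller n.

The same analysis runs end to end from a shell:

```bash
trialdistill run --config config.yaml --seed 3 --outdir out/
trialdistill sensitivity --config config.yaml --retention-grid 45,60,75
```

writing labels, scores, model summary, subset memberships, effect-estimate
tables (`estimates.csv`), characteristic summaries and a reproducibility
manifest.

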