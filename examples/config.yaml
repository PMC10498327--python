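# Full pipeline run on a synthetic trial emulating the default study
# conditions.  Swap `scenario:` for `input:` (participants/contacts/retention
# CSV paths) to analyze real trial tables.
seed: 3
outdir: trialdistill_out

scenario:
  n_per_arm: 400
  effect_engaged: 0.6     # IRR among would-be engagers
  effect_nonengaged: 1.0  # offer without delivery does nothing
  engagement_rate: 0.5

thresholds:               # the 2-of-3 engaged-participation rule
  min_hours_early: 3
  early_window_days: 14
  min_weeks_with_contact: 4
  contact_window_weeks: 6
  retention_days_required: 60
  criteria_required: 2

stage1:                   # reference boosting profile
  learning_rate: 0.001
  interaction_depth: 2
  max_trees: 10000
  cv_folds: 8
  cv_eval_stride: 25      # evaluate held-out AUC every 25 stages

fractions: [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2]
horizons: [30, 90, 180]
adjustment: default       # adjusted models use the full stage-1 covariate set
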