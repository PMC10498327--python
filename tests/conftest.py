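import dataclasses

import pytest

import trialdistill as td
from trialdistill.propensity import FAST_STAGE1
from trialdistill.records import TREATMENT, covariate_frame


@pytest.fixture(scope="session")
def default_trial():
    """One synthetic trial at the default study conditions (400/arm)."""
    return td.simulate_trial(td.SimulationScenario(seed=11))


@pytest.fixture(scope="session")
def labeled_trial(default_trial):
    records, truth = default_trial
    labels = td.label_treatment_arm(records)
    return records, truth, labels


@pytest.fixture(scope="session")
def fitted_model(labeled_trial):
    """Stage-1 model fit with the fast replicate profile, plus arm-blind scores."""
    records, truth, labels = labeled_trial
    cov = covariate_frame(records)
    cov, report = td.recode_rare_levels(cov, labels, 5)
    treat_ids = [r.participant_id for r in records if r.arm == TREATMENT]
    model = td.fit_engagement_model(
        cov.loc[treat_ids], labels, dataclasses.replace(FAST_STAGE1, seed=11), report,
        encoding_reference=cov,
    )
    scores = td.predict_engagement(model, cov)
    return model, scores, cov
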