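"""Stage-1 engagement-probability model: recoding, fitting, scoring, influence."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import trialdistill as td
from trialdistill.propensity import FAST_STAGE1, Stage1Config
from trialdistill.records import TREATMENT, covariate_frame


def small_covariates(levels, ids=None):
    ids = ids or [f"P{i}" for i in range(len(levels))]
    df = pd.DataFrame({"race_ethnicity": levels}, index=pd.Index(ids, name="participant_id"))
    return df


class TestRecodeRareLevels:
    def test_rare_level_merged_into_highest_engaged_rate_level(self):
        levels = ["a"] * 10 + ["b"] * 10 + ["rare"] * 3
        ids = [f"P{i}" for i in range(23)]
        df = small_covariates(levels, ids)
        # level b has the higher treatment-arm engaged rate
        labels = {ids[i]: (i < 3) for i in range(10)}  # a: 3/10 engaged
        labels.update({ids[10 + i]: (i < 8) for i in range(10)})  # b: 8/10
        out, report = td.recode_rare_levels(df, labels, min_count=5)
        assert set(out["race_ethnicity"]) == {"a", "b"}
        assert report[0]["from_level"] == "rare" and report[0]["to_level"] == "b"
        assert report[0]["n_moved"] == 3

    def test_no_rare_level_is_identity(self):
        df = small_covariates(["a"] * 6 + ["b"] * 6)
        out, report = td.recode_rare_levels(df, {}, min_count=5)
        assert report == [] and out.equals(df)

    def test_tied_rates_break_alphabetically(self):
        levels = ["b"] * 6 + ["a"] * 6 + ["rare"] * 2
        ids = [f"P{i}" for i in range(14)]
        df = small_covariates(levels, ids)
        labels = {pid: False for pid in ids}  # all rates tie at 0
        out, report = td.recode_rare_levels(df, labels, min_count=5)
        assert report[0]["to_level"] == "a"

    def test_emulated_trial_rare_race_category(self, labeled_trial):
        """The generator's small residual race category (a few members in ~800)
        is reassigned, leaving three analyzable levels."""
        records, _, labels = labeled_trial
        cov = covariate_frame(records)
        n_rare = (cov["race_ethnicity"] == "other").sum()
        assert 0 < n_rare < 5
        out, report = td.recode_rare_levels(cov, labels, min_count=5)
        assert set(out["race_ethnicity"]) == {"hispanic", "nh_black", "nh_white"}
        moved = [e for e in report if e.get("from_level") == "other"]
        assert moved and moved[0]["n_moved"] == n_rare


def _strong_signal_trial(seed=5):
    coef = {k: 1.8 * v for k, v in td.simulate.DEFAULT_PROPENSITY_COEF.items()}
    scenario = td.SimulationScenario(seed=seed, propensity_coef=coef)
    records, truth = td.simulate_trial(scenario)
    labels = td.label_treatment_arm(records)
    cov = covariate_frame(records)
    cov, report = td.recode_rare_levels(cov, labels, 5)
    treat_ids = [r.participant_id for r in records if r.arm == TREATMENT]
    return records, truth, labels, cov, report, treat_ids


class TestFit:
    def test_planted_signal_recovers_discrimination(self):
        _, _, labels, cov, report, tid = _strong_signal_trial()
        model = td.fit_engagement_model(
            cov.loc[tid], labels, dataclasses.replace(FAST_STAGE1, seed=5), report
        )
        assert model.cv_auc_mean > 0.75
        assert model.cv_auc_sd >= 0
        assert model.selected_tree_count <= FAST_STAGE1.max_trees

    def test_permuted_labels_give_chance_auc(self):
        _, _, labels, cov, report, tid = _strong_signal_trial()
        rng = np.random.default_rng(0)
        vals = rng.permutation([labels[i] for i in tid])
        shuffled = dict(zip(tid, vals))
        model = td.fit_engagement_model(
            cov.loc[tid], shuffled, dataclasses.replace(FAST_STAGE1, seed=5), report
        )
        assert abs(model.cv_auc_mean - 0.5) < 0.1

    def test_halving_learning_rate_needs_more_trees(self):
        _, _, labels, cov, report, tid = _strong_signal_trial()
        base = Stage1Config(learning_rate=0.1, max_trees=400, cv_folds=3,
                            cv_eval_stride=10, seed=5)
        slow = dataclasses.replace(base, learning_rate=0.05)
        m_base = td.fit_engagement_model(cov.loc[tid], labels, base, report)
        m_slow = td.fit_engagement_model(cov.loc[tid], labels, slow, report)
        assert m_slow.selected_tree_count > m_base.selected_tree_count

    def test_single_class_labels_rejected(self):
        _, _, labels, cov, report, tid = _strong_signal_trial()
        with pytest.raises(ValueError):
            td.fit_engagement_model(
                cov.loc[tid], {i: True for i in tid}, FAST_STAGE1, report
            )

    def test_fewer_records_than_folds_rejected(self):
        _, _, labels, cov, report, tid = _strong_signal_trial()
        few = tid[:3]
        with pytest.raises(ValueError):
            td.fit_engagement_model(
                cov.loc[few], {i: labels[i] for i in few},
                Stage1Config(cv_folds=8), report,
            )


class TestPredict:
    def test_scores_for_everyone_in_unit_interval(self, fitted_model, labeled_trial):
        records, _, _ = labeled_trial
        model, scores, cov = fitted_model
        assert len(scores) == len(records) == 800
        assert scores.between(0, 1).all()

    def test_arm_blindness_identical_rows_identical_scores(self, fitted_model):
        model, _, cov = fitted_model
        row = cov.iloc[[0]]
        twins = pd.concat([row, row]).set_axis(["twin_treatment", "twin_control"])
        s = td.predict_engagement(model, twins)
        assert s.iloc[0] == s.iloc[1]

    def test_in_sample_auc_at_least_cv_auc(self, fitted_model, labeled_trial):
        records, _, labels = labeled_trial
        model, scores, _ = fitted_model
        tid = [r.participant_id for r in records if r.arm == "treatment"]
        in_sample = roc_auc_score([labels[i] for i in tid], scores.loc[tid])
        assert in_sample >= model.cv_auc_mean

    def test_seeded_determinism(self, labeled_trial):
        records, _, labels = labeled_trial
        cov = covariate_frame(records)
        cov, report = td.recode_rare_levels(cov, labels, 5)
        tid = [r.participant_id for r in records if r.arm == "treatment"]
        cfg = dataclasses.replace(FAST_STAGE1, seed=11)
        a = td.predict_engagement(
            td.fit_engagement_model(cov.loc[tid], labels, cfg, report), cov
        )
        b = td.predict_engagement(
            td.fit_engagement_model(cov.loc[tid], labels, cfg, report), cov
        )
        assert (a == b).all()

    def test_unseen_level_rejected(self, fitted_model):
        model, _, cov = fitted_model
        odd = cov.iloc[[0]].copy()
        odd["race_ethnicity"] = "martian"
        with pytest.raises(ValueError, match="martian"):
            td.predict_engagement(model, odd)


class TestInfluence:
    def test_planted_drivers_rank_at_top(self):
        scenario = td.SimulationScenario(
            seed=7,
            propensity_coef={"age": 1.6, "n_admissions_prior_6mo": -1.4},
        )
        records, _ = td.simulate_trial(scenario)
        labels = td.label_treatment_arm(records)
        cov = covariate_frame(records)
        cov, report = td.recode_rare_levels(cov, labels, 5)
        tid = [r.participant_id for r in records if r.arm == "treatment"]
        model = td.fit_engagement_model(
            cov.loc[tid], labels, dataclasses.replace(FAST_STAGE1, seed=7), report
        )
        top3 = [c for c, _ in td.feature_influence(model, 3)]
        assert "age" in top3 and "n_admissions_prior_6mo" in top3

    def test_k_zero_and_k_too_large(self, fitted_model):
        model, _, _ = fitted_model
        assert td.feature_influence(model, 0) == []
        full = td.feature_influence(model, 10_000)
        assert len(full) == len(model.feature_influences)

    def test_influences_normalize_to_100(self, fitted_model):
        model, _, _ = fitted_model
        assert sum(v for _, v in model.feature_influences) == pytest.approx(100.0)
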