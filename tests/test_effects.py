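"""Stage-3 effect models against closed-form oracles and degenerate inputs."""

import math

import numpy as np
import pandas as pd
import pytest

import trialdistill as td
from trialdistill.distill import distill, subset_series
from trialdistill.effects import (
    AdjustmentSpec,
    analysis_frame,
    distillation_curve,
    fit_count_model,
    fit_rate_model,
    irr_from_counts,
    or_from_2x2,
    summarize_characteristics,
)
from trialdistill.studies import (
    two_arm_rate_frame,
    unadjusted_irr_from_summaries,
    unadjusted_or_from_summaries,
)


def trivial_subset(frame):
    return distill({pid: 1.0 for pid in frame.index}, 1.0)


class TestOr2x2:
    def test_published_arm_summaries_reproduce(self):
        # arm sizes 393/389 with 180-day rates 60.1% vs 61.7%
        or_, lo, hi = or_from_2x2(236, 157, 240, 149)
        assert round(or_, 2) == 0.93
        assert (round(lo, 2), round(hi, 2)) == (0.70, 1.24)

    def test_symmetric_table_is_null(self):
        or_, lo, hi = or_from_2x2(1, 1, 1, 1)
        assert or_ == 1.0 and lo < 1 < hi

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            or_from_2x2(0, 5, 3, 2)

    def test_agrees_with_fitted_model_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 200, size=4)
            or_, lo, hi = or_from_2x2(a, b, c, d)
            frame = two_arm_rate_frame(a / (a + b), c / (c + d), int(a + b), int(c + d))
            frame = frame.rename(columns={"event": "readmitted_0"})
            est = fit_rate_model(trivial_subset(frame), frame, 0, None)
            assert est.point == pytest.approx(or_, rel=1e-6)
            assert est.ci_low == pytest.approx(lo, rel=1e-6)
            assert est.ci_high == pytest.approx(hi, rel=1e-6)


class TestRateModel:
    def test_reconstructed_30day_rates(self):
        est = unadjusted_or_from_summaries(0.267, 0.301, 393, 389)
        assert round(est.point, 2) == 0.85

    def test_identical_rates_give_null_or(self):
        est = unadjusted_or_from_summaries(0.4, 0.4, 200, 200)
        assert est.point == pytest.approx(1.0, abs=1e-9)

    def test_single_class_outcome_is_flagged_not_silent(self):
        frame = two_arm_rate_frame(1.0, 1.0, 20, 20).rename(
            columns={"event": "readmitted_0"}
        )
        est = fit_rate_model(trivial_subset(frame), frame, 0, None)
        assert math.isnan(est.point) and est.flags

    def test_ci_excludes_one_iff_p_below_alpha(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a, b, c, d = rng.integers(2, 120, size=4)
            frame = two_arm_rate_frame(a / (a + b), c / (c + d), int(a + b), int(c + d))
            frame = frame.rename(columns={"event": "readmitted_0"})
            est = fit_rate_model(trivial_subset(frame), frame, 0, None)
            assert est.significant == (est.p_value < 0.05)


class TestCountModel:
    def test_reconstructed_180day_means(self):
        est = unadjusted_irr_from_summaries(1.45, 1.48, 393, 389)
        assert round(est.point, 2) == 0.98

    def test_equal_means_give_null_irr(self):
        est = unadjusted_irr_from_summaries(1.2, 1.2, 150, 150)
        assert est.point == pytest.approx(1.0, abs=1e-9)

    def test_unadjusted_irr_is_exact_mean_ratio(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            yt = rng.poisson(1.3, size=int(rng.integers(20, 150)))
            yc = rng.poisson(1.6, size=int(rng.integers(20, 150)))
            if yt.sum() == 0 or yc.sum() == 0:
                continue
            irr, lo, hi = irr_from_counts(yt, yc)
            assert irr == pytest.approx(yt.mean() / yc.mean(), rel=1e-12)
            frame = pd.DataFrame(
                {
                    "treat": [1] * len(yt) + [0] * len(yc),
                    "readmit_count_0": np.concatenate([yt, yc]),
                },
                index=[f"X{i}" for i in range(len(yt) + len(yc))],
            )
            est = fit_count_model(trivial_subset(frame), frame, 0, None)
            assert est.point == pytest.approx(irr, rel=1e-6)
            assert est.ci_low == pytest.approx(lo, rel=1e-6)

    def test_all_zero_arm_is_flagged(self):
        frame = pd.DataFrame(
            {"treat": [1] * 10 + [0] * 10, "readmit_count_0": [0] * 10 + [2] * 10},
            index=[f"X{i}" for i in range(20)],
        )
        est = fit_count_model(trivial_subset(frame), frame, 0, None)
        assert math.isnan(est.point) and "all-zero" in est.flags[0]


class TestAdjustment:
    def test_constant_covariates_leave_estimate_unchanged(self, default_trial):
        records, _ = default_trial
        frame = analysis_frame(records)
        frame = frame.assign(age=60.0, copd=1)
        subset = trivial_subset(frame)
        unadj = fit_rate_model(subset, frame, 180, None)
        adj = fit_rate_model(subset, frame, 180, AdjustmentSpec(("age", "copd")))
        assert adj.point == pytest.approx(unadj.point, rel=1e-9)
        assert "dropped constant columns" in adj.flags[0]

    def test_adjusted_model_runs_with_full_covariate_set(self, default_trial):
        records, _ = default_trial
        frame = analysis_frame(records)
        est = fit_rate_model(
            trivial_subset(frame), frame, 180, td.effects.DEFAULT_ADJUSTMENT
        )
        assert est.adjusted and np.isfinite(est.point) and est.ci_low < est.ci_high


class TestCurveAndCharacteristics:
    def test_single_fraction_curve_is_plain_itt(self, default_trial):
        records, _ = default_trial
        frame = analysis_frame(records)
        scores = {pid: 0.5 for pid in frame.index}
        curve = distillation_curve(frame, subset_series(scores, [1.0]), (180,), None)
        assert len(curve) == 2  # OR + IRR, unadjusted only
        assert set(curve["fraction"]) == {1.0}
        yt = frame.loc[frame.treat == 1, "readmit_count_180"]
        yc = frame.loc[frame.treat == 0, "readmit_count_180"]
        irr_row = curve[curve.measure == "IRR"].iloc[0]
        assert irr_row["point"] == pytest.approx(yt.mean() / yc.mean(), rel=1e-6)

    def test_failed_cells_carry_diagnostics_curve_still_returned(self):
        frame = two_arm_rate_frame(1.0, 1.0, 15, 15).rename(
            columns={"event": "readmitted_30"}
        )
        frame["readmit_count_30"] = frame["readmitted_30"]
        scores = {pid: 1.0 for pid in frame.index}
        curve = distillation_curve(frame, subset_series(scores, [1.0, 0.5]), (30,), None)
        assert len(curve) == 4
        assert curve[curve.measure == "OR"]["flags"].map(len).gt(0).all()

    def test_full_fraction_summary_equals_whole_sample(self, default_trial):
        records, _ = default_trial
        frame = analysis_frame(records)
        scores = {pid: float(i) for i, pid in enumerate(frame.index)}
        summary = summarize_characteristics(subset_series(scores, [1.0]), frame)
        age = summary[(summary.variable == "age")].iloc[0]
        assert age["mean"] == pytest.approx(frame["age"].mean())
        assert age["sd"] == pytest.approx(frame["age"].std(ddof=1))

    def test_categorical_percentages_sum_to_100(self, default_trial):
        records, _ = default_trial
        frame = analysis_frame(records)
        scores = {pid: float(i) for i, pid in enumerate(frame.index)}
        summary = summarize_characteristics(subset_series(scores, [1.0, 0.4]), frame)
        for (_, var), grp in summary[summary.variable == "race_ethnicity"].groupby(
            ["fraction", "variable"]
        ):
            assert grp["pct"].sum() == pytest.approx(100.0)
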