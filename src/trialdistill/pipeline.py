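"""End-to-end orchestration: label → fit → score → distill → estimate → report.

A run is driven by a single declarative :class:`PipelineConfig` (YAML on disk)
naming either input CSV paths or a simulation scenario, the engagement
thresholds, the stage-1 model settings, the distillation fractions, horizons
and adjustment covariates.  One seed governs every stochastic stage; rerunning
with the same config and seed reproduces every output byte for byte.

Outcome data are never read before stage 3; the only post-randomization
information used earlier is the treatment arm's contact logs, consumed solely
to construct the stage-1 training labels within that arm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distill import decile_assign, subset_series, subset_table
from .effects import (
    AdjustmentSpec,
    analysis_frame,
    distillation_curve,
    summarize_characteristics,
)
from .engagement import EngagementThresholds, criteria_table, label_treatment_arm
from .propensity import (
    Stage1Config,
    fit_engagement_model,
    predict_engagement,
    recode_rare_levels,
)
from .records import (
    TREATMENT,
    covariate_frame,
    read_trial_table,
    validate_outcomes,
    write_trial_tables,
)
from .simulate import SimulationScenario, simulate_trial

log = logging.getLogger("trialdistill")

DEFAULT_FRACTIONS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "trialdistill_out"
    seed: int = 0
    #: exactly one of (input_paths, scenario)
    input_paths: dict | None = None
    scenario: SimulationScenario | None = None
    thresholds: EngagementThresholds = field(default_factory=EngagementThresholds)
    stage1: Stage1Config = field(default_factory=Stage1Config)
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    horizons: tuple[int, ...] = (30, 90, 180)
    #: covariates for the adjusted models; None → unadjusted models only
    adjustment_covariates: tuple[str, ...] | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_paths is None) == (self.scenario is None):
            raise ValueError("exactly one of input_paths / scenario must be given")
        if any(not (0 < f <= 1) for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")


def config_from_yaml(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    seed = int(raw.get("seed", 0))
    scenario = None
    if "scenario" in raw:
        sc = dict(raw["scenario"] or {})
        sc.setdefault("seed", seed)
        scenario = SimulationScenario(**sc)
    stage1 = dict(raw.get("stage1", {}))
    stage1.setdefault("seed", seed)
    adj = raw.get("adjustment", None)
    if adj == "default":
        from .records import COVARIATE_SCHEMA

        adj = tuple(COVARIATE_SCHEMA)
    elif adj is not None:
        adj = tuple(adj)
    return PipelineConfig(
        outdir=raw.get("outdir", "trialdistill_out"),
        seed=seed,
        input_paths=raw.get("input"),
        scenario=scenario,
        thresholds=EngagementThresholds(**raw.get("thresholds", {})),
        stage1=Stage1Config(**stage1),
        fractions=tuple(raw.get("fractions", DEFAULT_FRACTIONS)),
        horizons=tuple(raw.get("horizons", (30, 90, 180))),
        adjustment_covariates=adj,
        log_level=raw.get("log_level", "INFO"),
    )


def _config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    blob = json.dumps(enc(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_records(config: PipelineConfig):
    if config.scenario is not None:
        records, truth = simulate_trial(config.scenario)
        return records, truth
    paths = config.input_paths
    records, report = read_trial_table(
        paths["participants"],
        paths.get("contacts"),
        paths.get("retention"),
        strict=False,
    )
    if report["dropped_incomplete"] or report["invalid"]:
        log.warning(
            "dropped %d incomplete and %d invalid rows",
            len(report["dropped_incomplete"]),
            len(report["invalid"]),
        )
    return records, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all three stages and write every artifact; returns the manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def _stage(name):
        t0 = time.perf_counter()

        def done(**info):
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            log.info("stage %s: %s", name, info)

        return done

    done = _stage("load")
    records, truth = _load_records(config)
    frame = analysis_frame(records)
    outcome_issues = validate_outcomes(records)
    (outdir / "validation.json").write_text(json.dumps(outcome_issues, indent=2))
    done(n_records=len(records), n_treatment=int(frame["treat"].sum()),
         outcome_issues=len(outcome_issues))
    if truth is not None:
        write_trial_tables(records, outdir / "data")

    done = _stage("label")
    labels = label_treatment_arm(records, config.thresholds)
    criteria_table(records, config.thresholds).to_csv(outdir / "labels.csv", index=False)
    done(n_labeled=len(labels), n_engaged=int(sum(labels.values())))

    done = _stage("fit")
    cov = covariate_frame(records)
    cov_recoded, recode_report = recode_rare_levels(
        cov, labels, config.stage1.rare_level_min_count
    )
    treat_ids = [r.participant_id for r in records if r.arm == TREATMENT]
    model = fit_engagement_model(
        cov_recoded.loc[treat_ids], labels, config.stage1, recode_report,
        encoding_reference=cov_recoded,
    )
    summary = model.summary()
    summary["recode_report"] = recode_report
    (outdir / "model_summary.json").write_text(json.dumps(summary, indent=2))
    done(cv_auc_mean=round(model.cv_auc_mean, 4),
         selected_tree_count=model.selected_tree_count)

    done = _stage("score")
    scores = predict_engagement(model, cov_recoded)
    scores.rename("score").rename_axis("participant_id").to_csv(outdir / "scores.csv")
    diag = {}
    if truth is not None:
        # stage-1 assumption as a measured diagnostic: do the scores track the
        # simulated person-level effects / latent propensities?
        diag["score_vs_propensity_spearman"] = float(
            scores.corr(truth["propensity"], method="spearman")
        )
        diag["score_vs_would_engage_auc"] = _auc(
            truth["would_engage"].to_numpy(), scores.to_numpy()
        )
        (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=2))
    done(n_scored=len(scores), **diag)

    done = _stage("distill")
    score_map = scores.to_dict()
    subsets = subset_series(score_map, config.fractions)
    arms = frame["arm"].to_dict()
    subset_table(subsets, score_map, arms).to_csv(outdir / "subsets.csv", index=False)
    deciles = decile_assign(score_map)
    pd.Series(deciles, name="decile").rename_axis("participant_id").to_csv(
        outdir / "deciles.csv"
    )
    (outdir / "series_manifest.json").write_text(
        json.dumps(
            [
                {"fraction": s.fraction, "n_total": s.n_total,
                 "score_cutoff": s.score_cutoff}
                for s in subsets
            ],
            indent=2,
        )
    )
    done(n_subsets=len(subsets), sizes=[s.n_total for s in subsets])

    done = _stage("estimate")
    adjustment = (
        AdjustmentSpec(config.adjustment_covariates)
        if config.adjustment_covariates
        else None
    )
    curve = distillation_curve(frame, subsets, config.horizons, adjustment)
    curve.to_csv(outdir / "estimates.csv", index=False)
    (outdir / "curve.json").write_text(curve.to_json(orient="records", indent=2))
    flagged = int(curve["point"].isna().sum())
    if flagged:
        log.warning("%d estimate cells flagged", flagged)
    done(n_estimates=len(curve), n_flagged=flagged)

    done = _stage("report")
    chars = summarize_characteristics(subsets, frame)
    chars.to_csv(outdir / "characteristics.csv", index=False)
    done(n_characteristic_rows=len(chars))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _auc(y: np.ndarray, score: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y.astype(int), score))


def run_sensitivity(
    config: PipelineConfig, thresholds_grid: Sequence[EngagementThresholds]
) -> dict:
    """Re-run the whole pipeline once per engagement-threshold setting.

    Each grid point shares the config's seed; failures are isolated per point.
    """
    if not thresholds_grid:
        raise ValueError("thresholds_grid must be nonempty")
    results = {}
    for i, thr in enumerate(thresholds_grid):
        sub = dataclasses.replace(
            config,
            thresholds=thr,
            outdir=str(Path(config.outdir) / f"sensitivity_{i:02d}"),
        )
        key = f"{i:02d}|" + json.dumps(dataclasses.asdict(thr), sort_keys=True)
        try:
            results[key] = run_pipeline(sub)
        except Exception as exc:
            log.error("sensitivity point %d failed: %s", i, exc)
            results[key] = {"error": str(exc)}
    return results
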