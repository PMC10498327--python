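"""Stage 1: engagement-probability modeling from prerandomization covariates.

A gradient-boosted classifier is trained on treatment-arm records only, with
the engaged-participation label as the outcome, and is then used to score
**every** participant in both arms.  Because the score is a fixed function of
prerandomization covariates, applying it identically to both arms preserves
the trial's randomization inside any score-defined subset (arm-blindness).

Reference configuration: depth-2 trees (2-way interactions of the covariates),
learning rate 0.001, up to 10,000 trees with the tree count self-selected by
8-fold cross-validated AUC.  The classifier sits behind a small
fit/predict/influence contract so alternative learners can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .records import CATEGORICAL_COVARIATES, COVARIATE_SCHEMA


@dataclass(frozen=True)
class Stage1Config:
    learning_rate: float = 0.001
    interaction_depth: int = 2
    max_trees: int = 10_000
    cv_folds: int = 8
    optimization_metric: str = "AUC"
    rare_level_min_count: int = 5
    seed: int = 0
    #: evaluate held-out AUC every this many boosting stages during CV; 1 keeps
    #: the exact per-tree optimum, larger strides trade resolution for speed
    cv_eval_stride: int = 1

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_trees < 1 or self.learning_rate <= 0 or self.interaction_depth < 1:
            raise ValueError("invalid boosting configuration")
        if self.optimization_metric != "AUC":
            raise ValueError("only AUC optimization is supported")


#: scaled-down profile for replicate studies (many simulated trials per run)
FAST_STAGE1 = Stage1Config(
    learning_rate=0.08, max_trees=200, cv_folds=3, cv_eval_stride=10
)


@dataclass
class EngagementModel:
    estimator: GradientBoostingClassifier
    columns: list[str]
    column_sources: dict[str, str]
    selected_tree_count: int
    cv_auc_mean: float
    cv_auc_sd: float
    feature_influences: list[tuple[str, float]]
    config: Stage1Config
    recode_map: dict[str, dict[str, str]] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "selected_tree_count": self.selected_tree_count,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_sd": self.cv_auc_sd,
            "feature_influences": [
                {"covariate": c, "relative_influence_pct": v}
                for c, v in self.feature_influences
            ],
        }


# ---------------------------------------------------------------------------
# rare-level handling


def recode_rare_levels(
    covariates: pd.DataFrame,
    treatment_labels: Mapping[str, bool],
    min_count: int = 5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Merge sparse categorical levels into better-populated ones.

    Any categorical level with fewer than ``min_count`` members (over the whole
    table) is merged into the retained level whose treatment-arm
    engaged-participation rate is highest; ties break to the alphabetically
    first candidate.  Variables left with a single level are dropped with a
    warning entry in the report.  Returns the recoded table and the report,
    one entry per reassignment.
    """
    df = covariates.copy()
    report: list[dict] = []
    labeled = pd.Series(
        {pid: bool(v) for pid, v in treatment_labels.items()}, dtype=bool
    )
    for col in CATEGORICAL_COVARIATES:
        if col not in df.columns:
            continue
        counts = df[col].value_counts()
        rare = sorted(counts.index[counts < min_count])
        retained = sorted(counts.index[counts >= min_count])
        if not rare:
            continue
        if not retained:
            report.append({"variable": col, "action": "dropped", "reason": "no level reaches min_count"})
            df = df.drop(columns=[col])
            continue
        # engaged rate per retained level, computed on labeled treatment rows
        in_treat = df.index.intersection(labeled.index)
        rates = {}
        for lev in retained:
            members = in_treat[df.loc[in_treat, col] == lev]
            rates[lev] = labeled.loc[members].mean() if len(members) else 0.0
        # deterministic tie-break: alphabetically first among maximal rates
        top = max(rates.values())
        best = sorted(lev for lev in retained if rates[lev] == top)[0]
        for lev in rare:
            n_moved = int((df[col] == lev).sum())
            df.loc[df[col] == lev, col] = best
            report.append(
                {
                    "variable": col,
                    "from_level": lev,
                    "to_level": best,
                    "n_moved": n_moved,
                    "engaged_rate_of_target": float(rates[best]),
                }
            )
        if df[col].nunique() < 2:
            report.append(
                {"variable": col, "action": "dropped", "reason": "single level after recoding"}
            )
            df = df.drop(columns=[col])
    return df, report


# ---------------------------------------------------------------------------
# encoding

def _encode(
    covariates: pd.DataFrame, levels: Mapping[str, list] | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """One-hot encode categoricals as ``name=level`` columns.

    ``levels`` fixes the dummy columns per categorical (e.g. the levels of the
    full two-arm population, so levels unobserved in the training arm still get
    a column); by default the observed levels are used.  Returns the design
    frame and a map from encoded column to source covariate.
    """
    parts = []
    sources: dict[str, str] = {}
    levels = levels or {}
    for col in covariates.columns:
        spec = COVARIATE_SCHEMA.get(col, ("continuous",))
        if spec[0] == "categorical":
            for lev in levels.get(col, sorted(covariates[col].astype(str).unique())):
                name = f"{col}={lev}"
                parts.append((covariates[col].astype(str) == lev).astype(float).rename(name))
                sources[name] = col
        else:
            parts.append(pd.to_numeric(covariates[col]).astype(float).rename(col))
            sources[col] = col
    design = pd.concat(parts, axis=1)
    return design, sources


def _design_for(model: EngagementModel, covariates: pd.DataFrame) -> pd.DataFrame:
    cov = covariates.copy()
    # map levels merged during training-time recoding
    for col, mapping in model.recode_map.items():
        if col in cov.columns:
            cov[col] = cov[col].replace(mapping)
    design, _ = _encode(cov)
    unseen = [
        c
        for c in design.columns
        if c not in model.columns and design[c].any()
    ]
    if unseen:
        raise ValueError(
            f"categorical levels unseen at training time: {unseen}; "
            "recode them or retrain"
        )
    return design.reindex(columns=model.columns, fill_value=0.0)


# ---------------------------------------------------------------------------
# fitting / scoring


def fit_engagement_model(
    treatment_covariates: pd.DataFrame,
    labels: Mapping[str, bool] | pd.Series | Sequence[bool],
    config: Stage1Config = Stage1Config(),
    recode_report: Sequence[dict] = (),
    encoding_reference: pd.DataFrame | None = None,
) -> EngagementModel:
    """Fit the boosted-tree engagement model on treatment-arm records.

    The tree count is chosen at the cross-validated AUC optimum (ties break to
    the smallest count); ``cv_auc_mean``/``cv_auc_sd`` are the held-out AUC
    mean and across-fold SD at that count.  Arm assignment is never an input.

    ``encoding_reference`` (typically the full two-arm covariate table) fixes
    the categorical level set of the design matrix so the model can later score
    records carrying levels that happen to be absent from the training arm.
    """
    if isinstance(labels, Mapping):
        y = pd.Series(labels).reindex(treatment_covariates.index)
        if y.isna().any():
            raise ValueError("labels missing for some treatment-arm records")
        y = y.astype(int).to_numpy()
    else:
        y = pd.Series(list(labels), index=treatment_covariates.index).astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both engaged and nonparticipant labels are required")
    if len(y) < config.cv_folds:
        raise ValueError("fewer records than CV folds")

    ref = encoding_reference if encoding_reference is not None else treatment_covariates
    levels = {
        col: sorted(ref[col].astype(str).unique())
        for col in ref.columns
        if COVARIATE_SCHEMA.get(col, ("continuous",))[0] == "categorical"
    }
    design, sources = _encode(treatment_covariates, levels)
    X = design.to_numpy()

    stages = np.arange(
        config.cv_eval_stride, config.max_trees + 1, config.cv_eval_stride
    )
    if stages[-1] != config.max_trees:
        stages = np.append(stages, config.max_trees)
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    fold_aucs = np.empty((config.cv_folds, len(stages)))
    for k, (tr, va) in enumerate(skf.split(X, y)):
        gbm = GradientBoostingClassifier(
            learning_rate=config.learning_rate,
            n_estimators=config.max_trees,
            max_depth=config.interaction_depth,
            random_state=config.seed,
        ).fit(X[tr], y[tr])
        scores = _staged_scores(gbm, X[va], stages)
        fold_aucs[k] = [roc_auc_score(y[va], scores[:, j]) for j in range(len(stages))]

    mean_auc = fold_aucs.mean(axis=0)
    best_j = int(np.argmax(mean_auc))  # argmax returns the first (smallest) optimum
    best_trees = int(stages[best_j])

    final = GradientBoostingClassifier(
        learning_rate=config.learning_rate,
        n_estimators=best_trees,
        max_depth=config.interaction_depth,
        random_state=config.seed,
    ).fit(X, y)

    importances = final.feature_importances_
    agg: dict[str, float] = {}
    for name, imp in zip(design.columns, importances):
        agg[sources[name]] = agg.get(sources[name], 0.0) + float(imp)
    total = sum(agg.values())
    influences = sorted(
        ((c, (100.0 * v / total) if total > 0 else 0.0) for c, v in agg.items()),
        key=lambda t: (-t[1], t[0]),
    )

    recode_map: dict[str, dict[str, str]] = {}
    for entry in recode_report:
        if "from_level" in entry:
            recode_map.setdefault(entry["variable"], {})[entry["from_level"]] = entry[
                "to_level"
            ]

    return EngagementModel(
        estimator=final,
        columns=list(design.columns),
        column_sources=sources,
        selected_tree_count=best_trees,
        cv_auc_mean=float(mean_auc[best_j]),
        cv_auc_sd=float(fold_aucs[:, best_j].std(ddof=1)),
        feature_influences=influences,
        config=config,
        recode_map=recode_map,
    )


def _staged_scores(
    gbm: GradientBoostingClassifier, X: np.ndarray, stages: np.ndarray
) -> np.ndarray:
    """Decision-function values at the requested boosting stages (n x len(stages))."""
    wanted = set(int(s) for s in stages)
    cols = []
    for i, s in enumerate(gbm.staged_decision_function(X), start=1):
        if i in wanted:
            cols.append(np.asarray(s).ravel())
    return np.column_stack(cols)


def predict_engagement(
    model: EngagementModel, covariates: pd.DataFrame
) -> pd.Series:
    """Score every record (both arms) with P(engaged participation).

    Scores depend only on prerandomization covariates; identical covariate rows
    receive identical scores regardless of arm.
    """
    design = _design_for(model, covariates)
    probs = model.estimator.predict_proba(design.to_numpy())[:, 1]
    return pd.Series(probs, index=covariates.index, name="engagement_score")


def feature_influence(model: EngagementModel, k: int) -> list[tuple[str, float]]:
    """Top-``k`` covariates by relative influence (percent, summing to 100 overall)."""
    if k <= 0:
        return []
    return model.feature_influences[:k]
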