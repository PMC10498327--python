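"""Stage 3: treatment-effect estimation within distilled subsets.

Readmission *rates* are analyzed with binomial-family (logistic) GLMs and
readmission *counts* with Poisson-family GLMs, each with and without baseline
covariate adjustment.  The effect measure is the exponentiated treatment
coefficient — an odds ratio (OR) for rates, an incidence rate ratio (IRR) for
counts — with 95% Wald confidence intervals ``exp(coef ± 1.959964 * SE)``
where the SE comes from the Fisher information matrix of the fit, and
two-tailed Wald p-values at α = .05.

With only a treatment indicator in the model the estimates have closed forms
— the OR is the 2×2 cross-product ratio and the IRR is the ratio of arm mean
counts — which serve as independent oracles for the fitted models.

Small, deeply distilled subsets can fail to support a model (single-class
outcomes, separation); such cells return *flagged* estimates carrying a
diagnostic rather than silent NaNs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distill import DistilledSubset
from .records import (
    BINARY_COVARIATES,
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    COVARIATE_SCHEMA,
    HORIZONS,
    TREATMENT,
    ParticipantRecord,
)

Z_95 = 1.959964  # standard normal 97.5% quantile, as used for all 95% CIs


@dataclass(frozen=True)
class EffectEstimate:
    measure: str  # "OR" | "IRR"
    horizon: int
    fraction: float
    adjusted: bool
    point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    flags: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        """CI excludes 1 (equivalently, Wald p < .05)."""
        return bool(self.ci_low > 1.0 or self.ci_high < 1.0)

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "horizon": self.horizon,
            "fraction": self.fraction,
            "adjusted": self.adjusted,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "significant": self.significant if self.point == self.point else None,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class AdjustmentSpec:
    """Covariate list for the adjusted models (all prerandomization)."""

    covariates: tuple[str, ...]

    def __post_init__(self):
        unknown = [c for c in self.covariates if c not in COVARIATE_SCHEMA]
        if unknown:
            raise ValueError(f"unknown adjustment covariates: {unknown}")


DEFAULT_ADJUSTMENT = AdjustmentSpec(covariates=tuple(COVARIATE_SCHEMA))


def analysis_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Flat per-participant frame: arm indicator, covariates, outcomes."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "arm": r.arm,
            "treat": int(r.arm == TREATMENT),
        }
        row.update(r.covariates)
        for h in HORIZONS:
            row[f"readmitted_{h}"] = int(r.outcomes.readmitted(h))
            row[f"readmit_count_{h}"] = r.outcomes.count(h)
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def _design(
    data: pd.DataFrame, adjustment: AdjustmentSpec | None
) -> tuple[pd.DataFrame, list[str]]:
    """Intercept + treatment indicator + (optionally) encoded covariates.

    Zero-variance columns within the subset are dropped (and reported) so the
    information matrix stays invertible; categorical covariates enter as
    reference-coded dummies against the alphabetically first level present.
    """
    flags: list[str] = []
    X = pd.DataFrame({"const": 1.0, "treat": data["treat"].astype(float)}, index=data.index)
    if adjustment is not None:
        for cov in adjustment.covariates:
            if cov in CATEGORICAL_COVARIATES:
                levels = sorted(data[cov].astype(str).unique())
                for lev in levels[1:]:
                    X[f"{cov}={lev}"] = (data[cov].astype(str) == lev).astype(float)
            else:
                X[cov] = pd.to_numeric(data[cov]).astype(float)
    constant = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    if constant:
        flags.append(f"dropped constant columns: {constant}")
        X = X.drop(columns=constant)
    return X, flags


def _fit_glm(
    y: pd.Series,
    X: pd.DataFrame,
    family: sm.families.Family,
    measure: str,
    horizon: int,
    fraction: float,
    adjusted: bool,
    flags: list[str],
) -> EffectEstimate:
    n = len(y)
    if "treat" not in X.columns:
        return _flagged(measure, horizon, fraction, adjusted, n, flags + ["single-arm subset"])
    try:
        res = sm.GLM(y.astype(float), X, family=family).fit(maxiter=200, tol=1e-11)
        coef = float(res.params["treat"])
        se = float(res.bse["treat"])
    except Exception as exc:  # separation / singular information matrix
        return _flagged(
            measure, horizon, fraction, adjusted, n, flags + [f"fit failed: {exc}"]
        )
    if not np.isfinite(coef) or not np.isfinite(se) or se > 50:
        return _flagged(
            measure, horizon, fraction, adjusted, n,
            flags + ["unstable fit (separation or near-zero cells)"],
        )
    from scipy import stats

    p = 2 * stats.norm.sf(abs(coef) / se) if se > 0 else float("nan")
    return EffectEstimate(
        measure=measure,
        horizon=horizon,
        fraction=fraction,
        adjusted=adjusted,
        point=math.exp(coef),
        ci_low=math.exp(coef - Z_95 * se),
        ci_high=math.exp(coef + Z_95 * se),
        p_value=float(p),
        n_used=n,
        flags=tuple(flags),
    )


def _flagged(measure, horizon, fraction, adjusted, n, flags) -> EffectEstimate:
    nan = float("nan")
    return EffectEstimate(
        measure=measure,
        horizon=horizon,
        fraction=fraction,
        adjusted=adjusted,
        point=nan,
        ci_low=nan,
        ci_high=nan,
        p_value=nan,
        n_used=n,
        flags=tuple(flags),
    )


def fit_rate_model(
    subset: DistilledSubset,
    data: pd.DataFrame,
    horizon: int,
    adjustment: AdjustmentSpec | None = None,
) -> EffectEstimate:
    """Logistic (binomial GLM) model of the readmission indicator; OR = exp(β_treat)."""
    sub = data.loc[list(subset.member_ids)]
    y = sub[f"readmitted_{horizon}"]
    flags: list[str] = []
    if y.nunique() < 2:
        return _flagged("OR", horizon, subset.fraction, adjustment is not None, len(sub),
                        ["single-class outcome in subset"])
    X, flags = _design(sub, adjustment)
    return _fit_glm(
        y, X, sm.families.Binomial(), "OR", horizon, subset.fraction,
        adjustment is not None, flags,
    )


def fit_count_model(
    subset: DistilledSubset,
    data: pd.DataFrame,
    horizon: int,
    adjustment: AdjustmentSpec | None = None,
) -> EffectEstimate:
    """Poisson GLM of the readmission count; IRR = exp(β_treat).

    Follow-up windows are fixed, so no exposure offset is used.
    """
    sub = data.loc[list(subset.member_ids)]
    y = sub[f"readmit_count_{horizon}"]
    flags = []
    for arm_val, name in ((1, "treatment"), (0, "control")):
        if (sub["treat"] == arm_val).any() and y[sub["treat"] == arm_val].sum() == 0:
            return _flagged("IRR", horizon, subset.fraction, adjustment is not None,
                            len(sub), [f"all-zero counts in {name} arm"])
    X, flags = _design(sub, adjustment)
    return _fit_glm(
        y, X, sm.families.Poisson(), "IRR", horizon, subset.fraction,
        adjustment is not None, flags,
    )


# ---------------------------------------------------------------------------
# closed-form oracles


def or_from_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Odds ratio and Wald 95% CI from a 2×2 table.

    ``a``/``b`` are treatment-arm events/non-events; ``c``/``d`` the control
    arm's.  OR = (a·d)/(b·c); log-scale SE = sqrt(1/a + 1/b + 1/c + 1/d).
    No continuity correction: zero cells are an error.
    """
    if min(a, b, c, d) <= 0:
        raise ValueError("all 2x2 cells must be positive")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-Z_95 * se), or_ * math.exp(Z_95 * se)


def irr_from_counts(
    treatment_counts: Sequence[int], control_counts: Sequence[int]
) -> tuple[float, float, float]:
    """IRR and Wald 95% CI from raw per-person counts (Poisson MLE closed form).

    With a lone binary regressor the Poisson MLE of the rate ratio is the
    ratio of arm means; the log-scale SE is sqrt(1/Σy_t + 1/Σy_c).
    """
    st, sc = float(np.sum(treatment_counts)), float(np.sum(control_counts))
    if st <= 0 or sc <= 0:
        raise ValueError("each arm needs a positive total count")
    irr = (st / len(treatment_counts)) / (sc / len(control_counts))
    se = math.sqrt(1 / st + 1 / sc)
    return irr, irr * math.exp(-Z_95 * se), irr * math.exp(Z_95 * se)


# ---------------------------------------------------------------------------
# curves and characteristic tables


def distillation_curve(
    data: pd.DataFrame,
    subsets: Sequence[DistilledSubset],
    horizons: Sequence[int] = HORIZONS,
    adjustment: AdjustmentSpec | None = DEFAULT_ADJUSTMENT,
) -> pd.DataFrame:
    """Effect estimates over the whole distillation series.

    One row per (measure, horizon, fraction, adjusted); failed cells carry
    their diagnostic in ``flags`` and the curve is still returned.
    """
    rows = []
    for s in subsets:
        for h in horizons:
            for adj in (None, adjustment) if adjustment is not None else (None,):
                rows.append(fit_rate_model(s, data, h, adj).as_dict())
                rows.append(fit_count_model(s, data, h, adj).as_dict())
    return pd.DataFrame(rows)


def summarize_characteristics(
    subsets: Sequence[DistilledSubset], data: pd.DataFrame
) -> pd.DataFrame:
    """Baseline-characteristics summary per distillation fraction.

    Continuous covariates: mean and SD.  Categorical/binary covariates: n and
    percentage (percentages within a categorical variable sum to 100 up to
    rounding).
    """
    rows = []
    for s in subsets:
        sub = data.loc[list(s.member_ids)]
        n = len(sub)
        for cov in CONTINUOUS_COVARIATES:
            rows.append(
                {
                    "fraction": s.fraction, "variable": cov, "level": "",
                    "n": n, "mean": float(sub[cov].mean()),
                    "sd": float(sub[cov].std(ddof=1)), "pct": float("nan"),
                }
            )
        for cov in CATEGORICAL_COVARIATES:
            for lev in sorted(sub[cov].astype(str).unique()):
                k = int((sub[cov].astype(str) == lev).sum())
                rows.append(
                    {
                        "fraction": s.fraction, "variable": cov, "level": lev,
                        "n": k, "mean": float("nan"), "sd": float("nan"),
                        "pct": 100.0 * k / n,
                    }
                )
        for cov in BINARY_COVARIATES:
            k = int(pd.to_numeric(sub[cov]).sum())
            rows.append(
                {
                    "fraction": s.fraction, "variable": cov, "level": "yes",
                    "n": k, "mean": float("nan"), "sd": float("nan"),
                    "pct": 100.0 * k / n,
                }
            )
    return pd.DataFrame(rows)
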