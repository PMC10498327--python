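"""Participant-level data model, validation and delimited-text I/O.

A trial dataset is a list of :class:`ParticipantRecord`: baseline covariates
collected before randomization, the assigned arm, readmission outcomes at the
30/90/180-day horizons, and — for treatment-arm records only — a care-coordination
contact log.  All dates are integer day offsets from the index discharge (day 0);
no calendar types are used anywhere.

On disk a dataset is up to three UTF-8 comma-separated files with headers:

* ``participants.csv`` — one row per participant: id, arm, covariates, outcomes
  (booleans serialized 0/1);
* ``contacts.csv`` — one row per contact: participant_id, day, hours;
* ``retention.csv`` — one row per treatment-arm participant: participant_id,
  retention_days, graduated, graduation_day (empty when not graduated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENT = "treatment"
CONTROL = "control"
ARMS = (TREATMENT, CONTROL)

HORIZONS = (30, 90, 180)

#: Baseline covariate schema: name -> ("continuous",) | ("binary",) |
#: ("categorical", (level, ...)).  The fields mirror the demographic, social and
#: clinical characteristics collected at the preenrollment bedside visit.
COVARIATE_SCHEMA: dict[str, tuple] = {
    "age": ("continuous",),
    "sex": ("categorical", ("male", "female")),
    "race_ethnicity": ("categorical", ("hispanic", "nh_black", "nh_white", "other")),
    "education": ("categorical", ("at_least_hs", "less_than_hs")),
    "relationship": ("categorical", ("partnered", "single")),
    "housing": ("categorical", ("stable", "homeless")),
    "family_support": ("categorical", ("sufficient", "insufficient")),
    "employment": ("categorical", ("employed", "not_employed")),
    "arrest_prior_6mo": ("binary",),
    "self_rated_health": ("categorical", ("fair_good_excellent", "poor")),
    "n_admissions_prior_6mo": ("continuous",),
    "index_los_days": ("continuous",),
    "alcohol_dx": ("binary",),
    "mental_health_dx": ("binary",),
    "substance_use_dx": ("binary",),
    "aids": ("binary",),
    "copd": ("binary",),
    "chf": ("binary",),
    "dementia": ("binary",),
    "diabetes_complicated": ("binary",),
    "hemiplegia": ("binary",),
    "mild_liver_disease": ("binary",),
    "severe_liver_disease": ("binary",),
    "kidney_disease": ("binary",),
    "rheumatoid_arthritis": ("binary",),
    "anxiety": ("binary",),
    "mood_disorder": ("binary",),
    "schizophrenia": ("binary",),
    "suicidal_ideation": ("binary",),
}

CONTINUOUS_COVARIATES = tuple(
    k for k, v in COVARIATE_SCHEMA.items() if v[0] == "continuous"
)
BINARY_COVARIATES = tuple(k for k, v in COVARIATE_SCHEMA.items() if v[0] == "binary")
CATEGORICAL_COVARIATES = tuple(
    k for k, v in COVARIATE_SCHEMA.items() if v[0] == "categorical"
)


class SchemaError(ValueError):
    """A required column is missing or a column has an undeclared type."""


class ValidationError(ValueError):
    """Row-level integrity violation (duplicate id, bad level, bad range)."""


@dataclass(frozen=True)
class OutcomeRecord:
    """Readmission outcomes anchored at the index discharge.

    ``readmitted_h`` must equal ``readmit_count_h >= 1`` and counts must be
    nondecreasing in the horizon (a 30-day readmission is also a 90- and
    180-day readmission).
    """

    readmitted_30: bool
    readmitted_90: bool
    readmitted_180: bool
    readmit_count_30: int
    readmit_count_90: int
    readmit_count_180: int

    def count(self, horizon: int) -> int:
        return getattr(self, f"readmit_count_{horizon}")

    def readmitted(self, horizon: int) -> bool:
        return getattr(self, f"readmitted_{horizon}")

    def issues(self) -> list[str]:
        out = []
        c = [self.readmit_count_30, self.readmit_count_90, self.readmit_count_180]
        if any(x < 0 for x in c):
            out.append("negative readmission count")
        if not (c[0] <= c[1] <= c[2]):
            out.append("counts not monotone in horizon")
        for h in HORIZONS:
            if self.readmitted(h) != (self.count(h) >= 1):
                out.append(f"indicator/count mismatch at {h} d")
        return out


@dataclass(frozen=True)
class EngagementLog:
    """Treatment-arm contact history relative to enrollment (day 0).

    ``contacts`` is a sequence of ``(day_offset, duration_hours)`` pairs for
    completed in-person or phone contacts.  ``retention_days`` is how long the
    participant remained in the program; ``graduation_day`` is present iff the
    participant formally graduated.
    """

    contacts: tuple[tuple[float, float], ...]
    retention_days: float
    graduated: bool = False
    graduation_day: float | None = None

    def issues(self) -> list[str]:
        out = []
        for day, hours in self.contacts:
            if day < 0:
                out.append(f"contact at negative day {day}")
            if hours < 0:
                out.append(f"negative contact duration {hours}")
            if day > self.retention_days:
                out.append(f"contact on day {day} after retention end")
        if self.retention_days < 0:
            out.append("negative retention_days")
        if self.graduated != (self.graduation_day is not None):
            out.append("graduation_day present iff graduated")
        return out


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    arm: str
    covariates: dict[str, object]
    outcomes: OutcomeRecord
    engagement_log: EngagementLog | None = None

    def issues(self) -> list[str]:
        out = []
        if self.arm not in ARMS:
            out.append(f"unknown arm {self.arm!r}")
        if self.arm == CONTROL and self.engagement_log is not None:
            out.append("control-arm record carries an engagement log")
        for name, spec in COVARIATE_SCHEMA.items():
            if name not in self.covariates:
                out.append(f"missing covariate {name}")
                continue
            v = self.covariates[name]
            kind = spec[0]
            if kind == "categorical" and v not in spec[1]:
                out.append(f"{name}={v!r} not in declared levels")
            elif kind == "binary" and v not in (True, False, 0, 1):
                out.append(f"{name}={v!r} not boolean")
            elif kind == "continuous" and (not np.isfinite(v) or v < 0):
                out.append(f"{name}={v!r} not a nonnegative number")
        if "age" in self.covariates:
            try:
                if self.covariates["age"] <= 0:
                    out.append("age must be positive")
            except TypeError:
                pass
        out.extend(self.outcomes.issues())
        if self.engagement_log is not None:
            out.extend(self.engagement_log.issues())
        return out


# ---------------------------------------------------------------------------
# tabular conversion


def records_to_frames(
    records: Sequence[ParticipantRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten records into (participants, contacts, retention) data frames."""
    rows, contact_rows, ret_rows = [], [], []
    for r in records:
        row: dict[str, object] = {"participant_id": r.participant_id, "arm": r.arm}
        for name, spec in COVARIATE_SCHEMA.items():
            v = r.covariates[name]
            row[name] = int(v) if spec[0] == "binary" else v
        for h in HORIZONS:
            row[f"readmitted_{h}"] = int(r.outcomes.readmitted(h))
            row[f"readmit_count_{h}"] = r.outcomes.count(h)
        rows.append(row)
        log = r.engagement_log
        if log is not None:
            for day, hours in log.contacts:
                contact_rows.append(
                    {"participant_id": r.participant_id, "day": day, "hours": hours}
                )
            ret_rows.append(
                {
                    "participant_id": r.participant_id,
                    "retention_days": log.retention_days,
                    "graduated": int(log.graduated),
                    "graduation_day": log.graduation_day,
                }
            )
    participants = pd.DataFrame(rows)
    contacts = pd.DataFrame(contact_rows, columns=["participant_id", "day", "hours"])
    retention = pd.DataFrame(
        ret_rows,
        columns=["participant_id", "retention_days", "graduated", "graduation_day"],
    )
    return participants, contacts, retention


def covariate_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Covariates only, indexed by participant_id (schema column order)."""
    df = pd.DataFrame(
        {r.participant_id: [r.covariates[c] for c in COVARIATE_SCHEMA] for r in records}
    ).T
    df.columns = list(COVARIATE_SCHEMA)
    df.index.name = "participant_id"
    for c in CONTINUOUS_COVARIATES:
        df[c] = pd.to_numeric(df[c])
    for c in BINARY_COVARIATES:
        df[c] = df[c].astype(int)
    return df


def write_trial_tables(records: Sequence[ParticipantRecord], outdir: str | Path) -> dict:
    """Write the three CSV tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants, contacts, retention = records_to_frames(records)
    paths = {
        "participants": outdir / "participants.csv",
        "contacts": outdir / "contacts.csv",
        "retention": outdir / "retention.csv",
    }
    participants.to_csv(paths["participants"], index=False)
    contacts.to_csv(paths["contacts"], index=False)
    retention.to_csv(paths["retention"], index=False)
    return {k: str(v) for k, v in paths.items()}


def _parse_outcomes(row: Mapping) -> OutcomeRecord:
    return OutcomeRecord(
        readmitted_30=bool(int(row["readmitted_30"])),
        readmitted_90=bool(int(row["readmitted_90"])),
        readmitted_180=bool(int(row["readmitted_180"])),
        readmit_count_30=int(row["readmit_count_30"]),
        readmit_count_90=int(row["readmit_count_90"]),
        readmit_count_180=int(row["readmit_count_180"]),
    )


def read_trial_table(
    participants_path: str | Path,
    contacts_path: str | Path | None = None,
    retention_path: str | Path | None = None,
    *,
    complete_case: bool = True,
    strict: bool = True,
) -> tuple[list[ParticipantRecord], dict]:
    """Read a trial dataset from delimited text.

    Returns ``(records, report)``.  ``report`` lists dropped/flagged rows with
    their 1-based data row numbers.  With ``complete_case`` (the default), rows
    with missing covariates or outcomes are dropped and counted rather than
    imputed.  With ``strict``, rows failing type/level checks raise
    :class:`ValidationError`; otherwise they are dropped and reported.
    """
    df = pd.read_csv(participants_path)
    required = (
        ["participant_id", "arm"]
        + list(COVARIATE_SCHEMA)
        + [f"readmitted_{h}" for h in HORIZONS]
        + [f"readmit_count_{h}" for h in HORIZONS]
    )
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")

    dup = df["participant_id"][df["participant_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate participant ids: {sorted(set(dup))}")

    contacts = pd.read_csv(contacts_path) if contacts_path else pd.DataFrame(
        columns=["participant_id", "day", "hours"]
    )
    retention = pd.read_csv(retention_path) if retention_path else pd.DataFrame(
        columns=["participant_id", "retention_days", "graduated", "graduation_day"]
    )
    contacts_by_id: dict[str, list[tuple[float, float]]] = {}
    for _, c in contacts.iterrows():
        contacts_by_id.setdefault(str(c["participant_id"]), []).append(
            (float(c["day"]), float(c["hours"]))
        )
    retention_by_id = {
        str(r["participant_id"]): r for _, r in retention.iterrows()
    }

    records: list[ParticipantRecord] = []
    report = {"n_rows": len(df), "dropped_incomplete": [], "invalid": []}
    for i, row in df.iterrows():
        rownum = int(i) + 1
        if row[required].isna().any():
            report["dropped_incomplete"].append(rownum)
            continue
        pid = str(row["participant_id"])
        log = None
        if pid in retention_by_id:
            ret = retention_by_id[pid]
            gday = ret["graduation_day"]
            log = EngagementLog(
                contacts=tuple(sorted(contacts_by_id.get(pid, []))),
                retention_days=float(ret["retention_days"]),
                graduated=bool(int(ret["graduated"])),
                graduation_day=None if pd.isna(gday) else float(gday),
            )
        rec = ParticipantRecord(
            participant_id=pid,
            arm=str(row["arm"]),
            covariates={k: _coerce_covariate(k, row[k]) for k in COVARIATE_SCHEMA},
            outcomes=_parse_outcomes(row),
            engagement_log=log,
        )
        problems = rec.issues()
        if problems:
            if strict:
                raise ValidationError(f"row {rownum} (id {pid}): {problems}")
            report["invalid"].append({"row": rownum, "id": pid, "issues": problems})
            continue
        records.append(rec)
    if not complete_case:
        # incomplete rows are still excluded from typed records but not hidden
        pass
    report["n_records"] = len(records)
    return records, report


def _coerce_covariate(name: str, value):
    kind = COVARIATE_SCHEMA[name][0]
    if kind == "continuous":
        return float(value)
    if kind == "binary":
        return bool(int(value))
    return str(value)


def validate_outcomes(records: Iterable[ParticipantRecord]) -> list[dict]:
    """Report-only outcome consistency check.

    Flags every record whose counts are not monotone across horizons or whose
    readmission indicator disagrees with its count.  An empty list means the
    dataset is internally consistent.
    """
    out = []
    for r in records:
        problems = r.outcomes.issues()
        if problems:
            out.append({"participant_id": r.participant_id, "issues": problems})
    return out


def write_validation_report(report: list[dict] | dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str))


def arm_split(records: Sequence[ParticipantRecord]) -> dict[str, int]:
    counts = {a: 0 for a in ARMS}
    for r in records:
        counts[r.arm] += 1
    return counts
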