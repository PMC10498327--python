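"""Engaged-participation labeling from care-coordination contact logs.

A treatment-arm enrollee is an *engaged participant* when they meet at least
2 of 3 criteria (all thresholds configurable):

1. **early dose** — at least 3 intervention hours during the first 2 weeks of
   enrollment;
2. **weekly contact** — staff contact in at least 4 of the first 6 weeks;
3. **retention** — retained in the program for 60 days, or graduated within
   that timeframe.

Weeks are calendar-agnostic 7-day blocks from enrollment: week ``w`` covers
days ``[7w, 7w+7)``.  Contacts with zero recorded duration count toward the
weekly-contact criterion but contribute nothing to the hours criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .records import TREATMENT, EngagementLog, ParticipantRecord


@dataclass(frozen=True)
class EngagementThresholds:
    min_hours_early: float = 3.0
    early_window_days: float = 14.0
    min_weeks_with_contact: int = 4
    contact_window_weeks: int = 6
    retention_days_required: float = 60.0
    criteria_required: int = 2

    def __post_init__(self):
        if not (
            self.min_hours_early > 0
            and self.early_window_days > 0
            and self.min_weeks_with_contact > 0
            and self.contact_window_weeks > 0
            and self.retention_days_required > 0
        ):
            raise ValueError("all engagement thresholds must be positive")
        if self.criteria_required not in (1, 2, 3):
            raise ValueError("criteria_required must be 1, 2 or 3")


@dataclass(frozen=True)
class CriteriaVector:
    early_dose_met: bool
    weekly_contact_met: bool
    retention_met: bool

    def n_met(self) -> int:
        return int(self.early_dose_met) + int(self.weekly_contact_met) + int(
            self.retention_met
        )


def evaluate_criteria(
    log: EngagementLog, thresholds: EngagementThresholds = EngagementThresholds()
) -> CriteriaVector:
    """Evaluate the three engagement criteria for one contact log."""
    if log is None:
        raise ValueError("criteria are defined only for treatment-arm records with a log")
    early_hours = sum(
        hours for day, hours in log.contacts if 0 <= day < thresholds.early_window_days
    )
    weeks_with_contact = {
        int(day // 7)
        for day, _ in log.contacts
        if 0 <= day < 7 * thresholds.contact_window_weeks
    }
    retention_met = log.retention_days >= thresholds.retention_days_required or (
        log.graduated
        and log.graduation_day is not None
        and log.graduation_day <= thresholds.retention_days_required
    )
    return CriteriaVector(
        early_dose_met=early_hours >= thresholds.min_hours_early,
        weekly_contact_met=len(weeks_with_contact) >= thresholds.min_weeks_with_contact,
        retention_met=bool(retention_met),
    )


def classify_engaged(
    criteria: CriteriaVector, thresholds: EngagementThresholds = EngagementThresholds()
) -> bool:
    """True iff the number of satisfied criteria reaches ``criteria_required``."""
    return criteria.n_met() >= thresholds.criteria_required


def label_treatment_arm(
    records: Sequence[ParticipantRecord],
    thresholds: EngagementThresholds = EngagementThresholds(),
) -> dict[str, bool]:
    """Label every treatment-arm record engaged/nonparticipant.

    Control-arm records never appear in the returned map.  Raises if any
    treatment-arm record lacks a contact log.
    """
    missing = [
        r.participant_id
        for r in records
        if r.arm == TREATMENT and r.engagement_log is None
    ]
    if missing:
        raise ValueError(f"treatment-arm records without engagement logs: {missing}")
    return {
        r.participant_id: classify_engaged(
            evaluate_criteria(r.engagement_log, thresholds), thresholds
        )
        for r in records
        if r.arm == TREATMENT
    }


def criteria_table(
    records: Sequence[ParticipantRecord],
    thresholds: EngagementThresholds = EngagementThresholds(),
) -> pd.DataFrame:
    """Per-participant criterion flags and the final label, for export."""
    rows = []
    for r in records:
        if r.arm != TREATMENT:
            continue
        cv = evaluate_criteria(r.engagement_log, thresholds)
        rows.append(
            {
                "participant_id": r.participant_id,
                "early_dose_met": int(cv.early_dose_met),
                "weekly_contact_met": int(cv.weekly_contact_met),
                "retention_met": int(cv.retention_met),
                "engaged": int(classify_engaged(cv, thresholds)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "early_dose_met",
            "weekly_contact_met",
            "retention_met",
            "engaged",
        ],
    )


def write_labels(labels: Mapping[str, bool], path: str | Path) -> None:
    pd.DataFrame(
        {"participant_id": list(labels), "engaged": [int(v) for v in labels.values()]}
    ).to_csv(path, index=False)
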