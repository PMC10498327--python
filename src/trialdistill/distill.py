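"""Stage 2: population distillation by ranked engagement probability.

All participants — both arms — are ordered by their estimated probability of
engaged participation and the analysis population is narrowed to nested
top-f% subsets (100% down to 20%) and, equivalently, to deciles of the ordered
scores.  The subset size convention is ``floor(fraction * N)``, which pins the
782 → 469 (60%) and 782 → 156 (20%) sizes.  Ties in score break by ascending
participant id, a deterministic rule that never looks at arm or outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import pandas as pd


@dataclass(frozen=True)
class DistilledSubset:
    fraction: float
    member_ids: tuple[str, ...]  # ranked, highest score first
    n_total: int
    score_cutoff: float

    def __contains__(self, pid: str) -> bool:
        return pid in set(self.member_ids)


def _ranked_ids(scores: Mapping[str, float]) -> list[str]:
    # highest score first; ties by ascending id
    return sorted(scores, key=lambda pid: (-scores[pid], pid))


def distill(scores: Mapping[str, float], fraction: float) -> DistilledSubset:
    """Top-``fraction`` slice of the ranked population."""
    if not scores:
        raise ValueError("scores must be nonempty")
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    ranked = _ranked_ids(scores)
    n = math.floor(fraction * len(ranked))
    members = tuple(ranked[:n])
    cutoff = scores[members[-1]] if members else float("inf")
    return DistilledSubset(
        fraction=float(fraction), member_ids=members, n_total=n, score_cutoff=cutoff
    )


def decile_assign(scores: Mapping[str, float]) -> dict[str, int]:
    """Assign each id to a score decile; 10 = most likely to engage.

    Boundaries are ``floor(k * N / 10)`` cut points on the same ranking used by
    :func:`distill`, so the union of the top ``k`` deciles equals the
    ``distill(k/10)`` membership exactly and decile sizes differ by at most 1.
    """
    if not scores:
        raise ValueError("scores must be nonempty")
    ranked = _ranked_ids(scores)
    n = len(ranked)
    cuts = [math.floor(k * n / 10) for k in range(11)]
    out: dict[str, int] = {}
    for k in range(10):
        for i in range(cuts[k], cuts[k + 1]):
            out[ranked[i]] = 10 - k
    return out


def subset_series(
    scores: Mapping[str, float], fractions: Sequence[float]
) -> list[DistilledSubset]:
    """Nested subsets for a descending list of fractions."""
    fr = list(fractions)
    if fr != sorted(fr, reverse=True):
        warnings.warn("fractions not sorted descending; sorting internally")
        fr = sorted(fr, reverse=True)
    return [distill(scores, f) for f in fr]


def subset_table(
    subsets: Sequence[DistilledSubset],
    scores: Mapping[str, float],
    arms: Mapping[str, str],
) -> pd.DataFrame:
    """Long-format export: one row per (fraction, member)."""
    rows = []
    for s in subsets:
        for pid in s.member_ids:
            rows.append(
                {
                    "fraction": s.fraction,
                    "participant_id": pid,
                    "arm": arms[pid],
                    "score": scores[pid],
                }
            )
    return pd.DataFrame(rows, columns=["fraction", "participant_id", "arm", "score"])


def arm_counts(subset: DistilledSubset, arms: Mapping[str, str]) -> dict[str, int]:
    counts = {"treatment": 0, "control": 0}
    for pid in subset.member_ids:
        counts[arms[pid]] += 1
    return counts
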