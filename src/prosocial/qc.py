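"""Performance-based exclusion rules.

A participant is excluded if they chose the dominated option on any
attention-check trial of the harm task, or missed strictly more than 10 % of
the effort-task trials (decisions there had a 6-s window; harm-task responses
were not time-limited, so no miss rule applies to them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

MISS_THRESHOLD = 0.10


@dataclass(frozen=True)
class QCReport:
    participant_id: object
    attention_fails: int
    missed_fraction: float
    excluded: bool
    reason: str  # none | attention_check | missed_trials | both


def check_attention(harm_records) -> int:
    """Count attention checks answered with the dominated option."""
    checks = [r for r in harm_records if r.trial.is_attention_check]
    if not checks:
        raise ValueError("no attention-check trials in harm records")
    return sum(1 for r in checks if r.choice != r.trial.dominant_choice)


def check_missed(effort_records) -> float:
    """Fraction of effort-task trials with no decision."""
    if not effort_records:
        raise ValueError("empty effort record set")
    return sum(1 for r in effort_records if r.missed) / len(effort_records)


def qc_report(participant_id, harm_records, effort_records) -> QCReport:
    fails = check_attention(harm_records)
    missed = check_missed(effort_records)
    fail_attention = fails >= 1
    fail_missed = missed > MISS_THRESHOLD
    if fail_attention and fail_missed:
        reason = "both"
    elif fail_attention:
        reason = "attention_check"
    elif fail_missed:
        reason = "missed_trials"
    else:
        reason = "none"
    return QCReport(participant_id, fails, missed, fail_attention or fail_missed, reason)


def apply_exclusions(
    harm_records: Mapping[object, list], effort_records: Mapping[object, list]
) -> tuple[list, list[QCReport]]:
    """Apply both rules to every participant with both tasks present.

    Returns the retained participant ids (input order) and one QCReport per
    participant.
    """
    if set(harm_records) != set(effort_records):
        raise ValueError("participants must have records for both tasks")
    reports = [
        qc_report(pid, harm_records[pid], effort_records[pid]) for pid in harm_records
    ]
    retained = [r.participant_id for r in reports if not r.excluded]
    return retained, reports
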