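"""Case-report deduplication.

Spontaneous-report databases contain two flavours of duplication: follow-up
versions of the same case (new report instance, shared case key) and
independently submitted reports describing the same adverse event in the
same patient.  Both inflate counts if left in.  Stage one keeps only the
latest version per case key.  Stage two applies a conservative
field-agreement heuristic: two reports are duplicates only if they agree on
the full canonical drug set, the full reaction-term set, sex, and age (both
present and equal), and were received within a configurable window of each
other; the earliest report in a duplicate group survives.  Every drop is
recorded as an auditable decision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

from .io import CaseReport
from .normalize import normalize_name
from .util import collapse_ws


class DropReason(str, enum.Enum):
    FOLLOWUP_VERSION = "FOLLOWUP_VERSION"
    HEURISTIC_DUPLICATE = "HEURISTIC_DUPLICATE"


@dataclass(frozen=True)
class DedupDecision:
    kept_isr: str
    dropped_isrs: tuple[str, ...]
    reason: DropReason


def _version_sort_key(case: CaseReport) -> tuple[date, str]:
    # undated reports sort earliest so a dated follow-up supersedes them
    return (case.receipt_date or date.min, case.isr_id)


def dedup_versions(
    cases: Sequence[CaseReport],
) -> tuple[list[CaseReport], list[DedupDecision]]:
    """Keep only the latest report version per case key.

    Latest by receipt date; date ties break to the lexicographically
    largest ISR, so the survivor is deterministic under input shuffling.
    """
    groups: dict[str, list[CaseReport]] = {}
    for c in cases:
        groups.setdefault(c.case_id, []).append(c)
    survivors: list[CaseReport] = []
    decisions: list[DedupDecision] = []
    for case_id in sorted(groups):
        versions = sorted(groups[case_id], key=_version_sort_key)
        survivors.append(versions[-1])
        if len(versions) > 1:
            decisions.append(
                DedupDecision(
                    kept_isr=versions[-1].isr_id,
                    dropped_isrs=tuple(v.isr_id for v in versions[:-1]),
                    reason=DropReason.FOLLOWUP_VERSION,
                )
            )
    survivors.sort(key=lambda c: c.isr_id)
    return survivors, decisions


def _duplicate_key(case: CaseReport) -> Optional[tuple]:
    """Agreement key for the duplicate heuristic; None if not comparable.

    Age must be present — an absent age is never treated as agreeing.
    Drugs compare by canonical name where assigned, otherwise by the
    normalized verbatim string (prefixed so an unmatched name can never
    collide with a canonical one).
    """
    if case.age is None:
        return None
    drugs = frozenset(
        m.canonical_drug if m.canonical_drug else "?" + normalize_name(m.verbatim_name)
        for m in case.drugs
    )
    reactions = frozenset(collapse_ws(r) for r in case.reactions)
    return (drugs, reactions, case.sex, case.age)


def dedup_heuristic(
    cases: Sequence[CaseReport], window_days: int = 30
) -> tuple[list[CaseReport], list[DedupDecision]]:
    """Drop likely same-patient duplicate reports.

    Within each agreement group, reports are clustered greedily by receipt
    date: the earliest report anchors a cluster and absorbs every later
    report within ``window_days`` of the anchor; a report beyond the window
    starts a new cluster.  Undated reports are never merged.
    """
    groups: dict[tuple, list[CaseReport]] = {}
    passthrough: list[CaseReport] = []
    for c in cases:
        key = _duplicate_key(c)
        if key is None or c.receipt_date is None:
            passthrough.append(c)
        else:
            groups.setdefault(key, []).append(c)

    survivors = list(passthrough)
    decisions: list[DedupDecision] = []
    for key in sorted(groups, key=repr):
        members = sorted(groups[key], key=lambda c: (c.receipt_date, c.isr_id))
        anchor = members[0]
        dropped: list[str] = []
        for c in members[1:]:
            if (c.receipt_date - anchor.receipt_date).days <= window_days:
                dropped.append(c.isr_id)
            else:
                survivors.append(anchor)
                if dropped:
                    decisions.append(
                        DedupDecision(anchor.isr_id, tuple(dropped), DropReason.HEURISTIC_DUPLICATE)
                    )
                anchor, dropped = c, []
        survivors.append(anchor)
        if dropped:
            decisions.append(
                DedupDecision(anchor.isr_id, tuple(dropped), DropReason.HEURISTIC_DUPLICATE)
            )
    survivors.sort(key=lambda c: c.isr_id)
    return survivors, decisions


def decisions_frame(decisions: Sequence[DedupDecision]):
    """Flatten decisions to a (kept_isr, dropped_isr, reason) table."""
    import pandas as pd

    rows = [
        {"kept_isr": d.kept_isr, "dropped_isr": isr, "reason": d.reason.value}
        for d in decisions
        for isr in d.dropped_isrs
    ]
    return pd.DataFrame(rows, columns=["kept_isr", "dropped_isr", "reason"])
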