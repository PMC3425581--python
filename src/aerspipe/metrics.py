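"""Report counts, prescribing ratios, normalized rates, and ranked risks.

Spontaneous-report counts cannot be compared across drugs without a market
denominator: a drug prescribed ten times as often produces more reports at
the same per-patient risk.  The denominator here is each drug's summed
new-prescription total (NRx) over the study window, expressed as a
*prescribing ratio* (PR): the drug's NRx divided by the largest NRx in the
comparison set, so the most-prescribed drug has PR = 1.  The *normalized
rate* for a (drug, category) cell is the report count divided by PR, and
the *ranked risk* rescales rates within a category so the highest-rate drug
scores 100.

Counts respect the reporter's causality assessment: a drug is counted under
"primary suspect" scope only when it carries the primary-suspect role, and
under "all suspect" scope when it is primary or secondary suspect
(concomitant/interacting mentions are excluded by default, with a switch).

Rounding contract: PRs half-up to 4 decimals; displayed rates and ranked
risks half-up to integers; rates kept at full precision internally so
ranked risks never accumulate double rounding.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .categories import EventCategory, case_matches
from .io import CaseReport, DrugRole
from .util import round_half_up

log = logging.getLogger(__name__)

ROLE_SCOPE_PRIMARY = "primary"
ROLE_SCOPE_ALL = "all"

_SCOPE_ROLES = {
    ROLE_SCOPE_PRIMARY: frozenset({DrugRole.PRIMARY_SUSPECT}),
    ROLE_SCOPE_ALL: frozenset({DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT}),
}


@dataclass(frozen=True)
class PrescriptionTable:
    """Per-drug summed NRx counts and derived prescribing ratios."""

    nrx: dict[str, int]
    pr: dict[str, float]  # 4-decimal prescribing ratios
    reference_drug: str  # argmax NRx (PR = 1.0000)

    @classmethod
    def from_csv(cls, path: Path | str) -> "PrescriptionTable":
        """Load a two-column (drug, nrx) CSV and derive ratios."""
        nrx: dict[str, int] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or reader.fieldnames[:2] != ["drug", "nrx"]:
                raise ValueError(f"expected 'drug,nrx' header in {path}")
            for row in reader:
                nrx[row["drug"]] = int(row["nrx"])
        return prescribing_ratios(nrx)


def prescribing_ratios(nrx: Mapping[str, int]) -> PrescriptionTable:
    """Derive prescribing ratios: PR(d) = NRx(d) / max NRx, half-up 4 dp."""
    if not nrx:
        raise ValueError("prescription table is empty")
    if any(v <= 0 for v in nrx.values()):
        bad = [d for d, v in nrx.items() if v <= 0]
        raise ValueError(f"non-positive NRx for {bad}")
    reference = max(nrx, key=lambda d: (nrx[d], d))
    top = Decimal(nrx[reference])
    pr = {d: float(round_half_up(Decimal(v) / top, 4)) for d, v in nrx.items()}
    return PrescriptionTable(nrx=dict(nrx), pr=pr, reference_drug=reference)


def _drug_in_scope(case: CaseReport, drug: str, roles: frozenset[DrugRole]) -> bool:
    return any(m.canonical_drug == drug and m.role in roles for m in case.drugs)


def count_reports(
    cases: Sequence[CaseReport],
    drug: str,
    category: EventCategory,
    role_scope: str = ROLE_SCOPE_PRIMARY,
    include_concomitant: bool = False,
) -> int:
    """Count cases matching ``category`` that implicate ``drug``.

    Each case contributes at most once regardless of how many reactions
    match or how many times the drug is mentioned.
    """
    roles = _SCOPE_ROLES[role_scope]
    if include_concomitant:
        roles = roles | {DrugRole.CONCOMITANT, DrugRole.INTERACTING}
    if not any(m.canonical_drug == drug for c in cases for m in c.drugs):
        log.warning("drug %r not found on any case; count is 0", drug)
        return 0
    return sum(
        1
        for c in cases
        if _drug_in_scope(c, drug, roles) and case_matches(c, category)
    )


def normalized_rate(count: int, pr: float) -> float:
    """Reports per unit prescribing ratio (full precision; round for display)."""
    if pr <= 0:
        raise ValueError(f"prescribing ratio must be > 0, got {pr}")
    return count / pr


def ranked_risk(rates: Mapping[str, float]) -> dict[str, int]:
    """Rescale rates within a category so the highest-rate drug scores 100.

    round-half-up(100 × rate / max rate); all-zero input ranks every drug 0
    with a warning.
    """
    if not rates:
        raise ValueError("no rates given")
    top = max(rates.values())
    if top <= 0:
        log.warning("all rates are zero; ranked risks are all 0")
        return {d: 0 for d in rates}
    return {d: int(round_half_up(100.0 * r / top)) for d, r in rates.items()}


def risk_table_from_counts(
    primary_counts: Mapping[str, int],
    all_counts: Mapping[str, int],
    pr_table: PrescriptionTable,
) -> pd.DataFrame:
    """Build the per-category risk table from pre-computed counts.

    Columns mirror the published layout: counts, PR, normalized rates
    (full precision), and integer ranked risks per suspect scope.  Rows
    sort by descending primary ranked risk.
    """
    drugs = list(primary_counts)
    for d in drugs:
        if all_counts[d] < primary_counts[d]:
            raise ValueError(f"all_count < primary_count for {d!r}")
    p_rate = {d: normalized_rate(primary_counts[d], pr_table.pr[d]) for d in drugs}
    a_rate = {d: normalized_rate(all_counts[d], pr_table.pr[d]) for d in drugs}
    rr_p = ranked_risk(p_rate)
    rr_a = ranked_risk(a_rate)
    df = pd.DataFrame(
        {
            "drug": drugs,
            "primary_count": [primary_counts[d] for d in drugs],
            "all_count": [all_counts[d] for d in drugs],
            "pr": [pr_table.pr[d] for d in drugs],
            "primary_rate": [p_rate[d] for d in drugs],
            "all_rate": [a_rate[d] for d in drugs],
            "ranked_primary": [rr_p[d] for d in drugs],
            "ranked_all": [rr_a[d] for d in drugs],
        }
    )
    return df.sort_values(
        ["ranked_primary", "drug"], ascending=[False, True], ignore_index=True
    )


def risk_table(
    cases: Sequence[CaseReport],
    drugs: Sequence[str],
    category: EventCategory,
    pr_table: PrescriptionTable,
    include_concomitant: bool = False,
) -> pd.DataFrame:
    """Count and rank one category across drugs (both suspect scopes)."""
    primary = {
        d: count_reports(cases, d, category, ROLE_SCOPE_PRIMARY, include_concomitant)
        for d in drugs
    }
    allc = {
        d: count_reports(cases, d, category, ROLE_SCOPE_ALL, include_concomitant)
        for d in drugs
    }
    df = risk_table_from_counts(primary, allc, pr_table)
    df.attrs["category"] = category.name
    return df


def format_risk_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the display rounding contract (integer rates, 4-dp PR)."""
    out = df.copy()
    out["primary_rate"] = [int(round_half_up(x)) for x in out["primary_rate"]]
    out["all_rate"] = [int(round_half_up(x)) for x in out["all_rate"]]
    out["pr"] = [float(round_half_up(x, 4)) for x in out["pr"]]
    return out


def combined_risk(
    cases: Sequence[CaseReport],
    drugs: Sequence[str],
    categories: Sequence[EventCategory],
    pr_table: PrescriptionTable,
    role_scope: str = ROLE_SCOPE_PRIMARY,
    unique_cases: bool = False,
    include_concomitant: bool = False,
) -> dict[str, float]:
    """Percent-of-maximum risk summed across categories.

    Default counting sums per-category counts, so a case matching k
    categories contributes k; ``unique_cases=True`` counts each case once
    if it matches any category.  Result: per drug, summed count / PR as a
    percent of the best drug, half-up to one decimal.
    """
    totals: dict[str, int] = {}
    for d in drugs:
        if unique_cases:
            union_terms = [t for c in categories for t in c.terms]
            # all categories must share a match mode for the union category
            modes = {c.match_mode for c in categories}
            if len(modes) != 1:
                raise ValueError("unique_cases requires a single match mode")
            from .categories import make_category

            union = make_category("__union__", union_terms, modes.pop())
            totals[d] = count_reports(cases, d, union, role_scope, include_concomitant)
        else:
            totals[d] = sum(
                count_reports(cases, d, cat, role_scope, include_concomitant)
                for cat in categories
            )
    rates = {d: normalized_rate(totals[d], pr_table.pr[d]) for d in drugs}
    top = max(rates.values())
    if top <= 0:
        log.warning("no matching cases for any drug; combined risks are all 0")
        return {d: 0.0 for d in drugs}
    return {d: float(round_half_up(100.0 * r / top, 1)) for d, r in rates.items()}


def yearly_trend(
    cases: Sequence[CaseReport], drug: str, category: EventCategory
) -> dict[object, int]:
    """Primary-suspect counts for (drug, category) partitioned by receipt year.

    Undated cases bucket under ``"UNKNOWN"``; buckets sum to the primary
    count by construction.
    """
    roles = _SCOPE_ROLES[ROLE_SCOPE_PRIMARY]
    out: dict[object, int] = {}
    for c in cases:
        if _drug_in_scope(c, drug, roles) and case_matches(c, category):
            year = c.receipt_date.year if c.receipt_date else "UNKNOWN"
            out[year] = out.get(year, 0) + 1
    return dict(sorted(out.items(), key=lambda kv: (isinstance(kv[0], str), kv[0])))


def stratify(
    cases: Sequence[CaseReport],
    drug: str,
    category: EventCategory,
    axis: str,
    role_scope: str = ROLE_SCOPE_PRIMARY,
) -> pd.DataFrame:
    """Break a (drug, category) count down by outcome or reporter.

    ``axis="OUTCOME"``: a case with several outcome codes contributes to
    each of its strata (outcomes are not exclusive).  ``axis="REPORTER"``:
    strata are exclusive and partition the count; a percent column is added.
    """
    roles = _SCOPE_ROLES[role_scope]
    matched = [
        c for c in cases if _drug_in_scope(c, drug, roles) and case_matches(c, category)
    ]
    counts: dict[str, int] = {}
    if axis == "OUTCOME":
        for c in matched:
            for outcome in c.outcomes:
                counts[outcome.name] = counts.get(outcome.name, 0) + 1
        df = pd.DataFrame(
            {"stratum": sorted(counts), "count": [counts[s] for s in sorted(counts)]},
        )
    elif axis == "REPORTER":
        for c in matched:
            occ = c.reporter_occupation.name
            counts[occ] = counts.get(occ, 0) + 1
        total = len(matched)
        strata = sorted(counts)
        df = pd.DataFrame(
            {
                "stratum": strata,
                "count": [counts[s] for s in strata],
                "percent": [
                    float(round_half_up(100.0 * counts[s] / total, 1)) if total else 0.0
                    for s in strata
                ],
            }
        )
    else:
        raise ValueError(f"axis must be OUTCOME or REPORTER, got {axis!r}")
    df.attrs.update(drug=drug, category=category.name, axis=axis)
    return df


def sensitivity_peak_rx(
    nrx_by_year: Mapping[tuple[str, int], int],
    cases: Sequence[CaseReport],
    drugs: Sequence[str],
    category: EventCategory,
    include_concomitant: bool = False,
) -> tuple[PrescriptionTable, pd.DataFrame]:
    """Sensitivity variant: PR from each drug's peak annual NRx.

    Identical counting/ranking pipeline; only the denominator changes.
    The returned table carries ``attrs["variant"] = "peak_annual_rx"``.
    """
    peak: dict[str, int] = {}
    for (drug, _year), v in nrx_by_year.items():
        peak[drug] = max(peak.get(drug, 0), v)
    missing = [d for d in drugs if d not in peak]
    if missing:
        raise ValueError(f"no yearly NRx for {missing}")
    pr_table = prescribing_ratios({d: peak[d] for d in drugs})
    df = risk_table(cases, drugs, category, pr_table, include_concomitant)
    df.attrs["variant"] = "peak_annual_rx"
    return pr_table, df
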