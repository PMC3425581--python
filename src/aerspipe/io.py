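"""Reading AERS-style quarterly extract files and writing result tables.

The legacy AERS quarterly convention is one delimited ASCII file per table
(demographics, drug mentions, reactions, outcomes, report sources), fields
separated by a dollar sign, first line naming the columns.  Rows from the
per-table files are joined on the report instance key (ISR) into
:class:`CaseReport` records.  Both the ISR (one submitted report version)
and the case-level key shared by follow-up versions are retained, because
deduplication operates on the case key.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)


class TableName(str, enum.Enum):
    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    OUTC = "OUTC"
    RPSR = "RPSR"


class DrugRole(str, enum.Enum):
    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"


class Outcome(str, enum.Enum):
    DEATH = "DE"
    LIFE_THREATENING = "LT"
    HOSPITALIZATION = "HO"
    DISABILITY = "DS"
    CONGENITAL_ANOMALY = "CA"
    REQUIRED_INTERVENTION = "RI"
    OTHER = "OT"


class ReporterOccupation(str, enum.Enum):
    PHYSICIAN = "MD"
    PHARMACIST = "PH"
    OTHER_HEALTH_PROFESSIONAL = "HP"
    CONSUMER = "CN"
    LAWYER = "LW"
    UNKNOWN = "UNK"


#: Default column layouts, one per table, legacy quarterly convention.
DEFAULT_COLUMNS: dict[TableName, tuple[str, ...]] = {
    TableName.DEMO: ("ISR", "CASE", "FDA_DT", "AGE", "GNDR_COD", "OCCP_COD"),
    TableName.DRUG: ("ISR", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"),
    TableName.REAC: ("ISR", "PT"),
    TableName.OUTC: ("ISR", "OUTC_COD"),
    TableName.RPSR: ("ISR", "RPSR_COD"),
}

_OCCP_MAP = {
    "MD": ReporterOccupation.PHYSICIAN,
    "PH": ReporterOccupation.PHARMACIST,
    "OT": ReporterOccupation.OTHER_HEALTH_PROFESSIONAL,
    "HP": ReporterOccupation.OTHER_HEALTH_PROFESSIONAL,
    "CN": ReporterOccupation.CONSUMER,
    "LW": ReporterOccupation.LAWYER,
}

_ROLE_MAP = {r.value: r for r in DrugRole}
_OUTC_MAP = {o.value: o for o in Outcome}


@dataclass(frozen=True)
class FileDialect:
    """Physical layout of the quarterly extract files."""

    delimiter: str = "$"
    encoding: str = "utf-8"
    columns: Mapping[TableName, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COLUMNS)
    )


@dataclass(frozen=True)
class RawReportRow:
    table_name: TableName
    isr_id: str
    case_id: str  # empty outside DEMO
    fields: dict[str, str]


@dataclass(frozen=True)
class Reject:
    table_name: TableName
    line_number: int
    reason: str


@dataclass
class ReadResult:
    rows: list[RawReportRow]
    rejects: list[Reject]
    replacement_chars: int = 0

    @property
    def n_rejects(self) -> int:
        return len(self.rejects)


@dataclass(frozen=True)
class DrugMention:
    verbatim_name: str
    role: DrugRole
    canonical_drug: Optional[str] = None


@dataclass
class CaseReport:
    """One safety report version, joined across the per-table files."""

    isr_id: str
    case_id: str
    receipt_date: Optional[date]
    age: Optional[float]
    sex: str  # "M" | "F" | "UNK"
    reporter_occupation: ReporterOccupation
    drugs: list[DrugMention]
    reactions: list[str]
    outcomes: frozenset[Outcome]
    report_sources: frozenset[str] = frozenset()
    date_flagged: bool = False  # receipt date missing or unparseable

    def with_drugs(self, drugs: Sequence[DrugMention]) -> "CaseReport":
        return dataclasses.replace(self, drugs=list(drugs))


@dataclass
class AssembleResult:
    cases: list[CaseReport]
    excluded: dict[str, str]  # isr -> reason
    n_warnings: int = 0

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


class DialectError(ValueError):
    """Header row does not match the dialect's declared columns."""


def read_quarter(
    paths: Mapping[TableName, Path | str], dialect: FileDialect | None = None
) -> ReadResult:
    """Read one quarter's per-table files into raw rows.

    A missing file is fatal (the error names the table).  A data line with
    the wrong field count is skipped and recorded in the rejects log with
    its line number.  Field content is preserved byte-for-byte apart from
    line terminators; undecodable bytes become U+FFFD and are counted.
    """
    dialect = dialect or FileDialect()
    rows: list[RawReportRow] = []
    rejects: list[Reject] = []
    n_replacements = 0
    for table in TableName:
        if table not in paths:
            continue
        path = Path(paths[table])
        if not path.exists():
            raise FileNotFoundError(f"{table.value} file not found: {path}")
        columns = tuple(dialect.columns[table])
        text = path.read_bytes().decode(dialect.encoding, errors="replace")
        n_replacements += text.count("�")
        lines = text.splitlines()
        if not lines:
            raise DialectError(f"{table.value} file {path} is empty (no header)")
        header = tuple(lines[0].split(dialect.delimiter))
        if header != columns:
            raise DialectError(
                f"{table.value} header {header!r} does not match dialect columns {columns!r}"
            )
        isr_pos = columns.index("ISR")
        case_pos = columns.index("CASE") if "CASE" in columns else None
        for lineno, line in enumerate(lines[1:], start=2):
            if line == "":
                continue
            parts = line.split(dialect.delimiter)
            if len(parts) != len(columns):
                rejects.append(
                    Reject(table, lineno, f"expected {len(columns)} fields, got {len(parts)}")
                )
                continue
            isr = parts[isr_pos]
            if isr == "":
                rejects.append(Reject(table, lineno, "empty ISR"))
                continue
            rows.append(
                RawReportRow(
                    table_name=table,
                    isr_id=isr,
                    case_id=parts[case_pos] if case_pos is not None else "",
                    fields=dict(zip(columns, parts)),
                )
            )
    if n_replacements:
        log.warning("replaced %d undecodable characters while reading", n_replacements)
    return ReadResult(rows=rows, rejects=rejects, replacement_chars=n_replacements)


def _parse_date(raw: str) -> Optional[date]:
    raw = raw.strip()
    if len(raw) == 8 and raw.isdigit():
        try:
            return date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
        except ValueError:
            return None
    return None


def assemble_cases(rows: Iterable[RawReportRow]) -> AssembleResult:
    """Join raw rows on ISR into case reports.

    A report is assembled for every ISR with at least one drug mention and
    one reaction; ISRs failing that are excluded and counted.  Reports
    without a demographics row get unknown demographics and fall back to
    the ISR as their case key.  Unknown outcome or occupation codes map to
    OTHER/UNKNOWN with a logged warning.
    """
    by_isr: dict[str, dict[TableName, list[RawReportRow]]] = {}
    for row in rows:
        by_isr.setdefault(row.isr_id, {}).setdefault(row.table_name, []).append(row)

    cases: list[CaseReport] = []
    excluded: dict[str, str] = {}
    n_warn = 0
    for isr in sorted(by_isr):
        tables = by_isr[isr]
        drug_rows = tables.get(TableName.DRUG, [])
        reac_rows = tables.get(TableName.REAC, [])
        if not drug_rows or not reac_rows:
            missing = "drugs" if not drug_rows else "reactions"
            excluded[isr] = f"no {missing}"
            continue

        demo = tables.get(TableName.DEMO, [None])[0]
        case_id, receipt, age, sex = isr, None, None, "UNK"
        occupation = ReporterOccupation.UNKNOWN
        date_flagged = True
        if demo is not None:
            f = demo.fields
            case_id = f.get("CASE", "") or isr
            receipt = _parse_date(f.get("FDA_DT", ""))
            date_flagged = receipt is None
            try:
                age = float(f["AGE"]) if f.get("AGE", "").strip() else None
            except ValueError:
                age = None
            raw_sex = f.get("GNDR_COD", "").strip().upper()
            sex = raw_sex if raw_sex in ("M", "F") else "UNK"
            occ_code = f.get("OCCP_COD", "").strip().upper()
            if occ_code:
                if occ_code in _OCCP_MAP:
                    occupation = _OCCP_MAP[occ_code]
                else:
                    log.warning("ISR %s: unknown occupation code %r", isr, occ_code)
                    n_warn += 1

        drugs = []
        for dr in sorted(drug_rows, key=lambda r: r.fields.get("DRUG_SEQ", "")):
            role_code = dr.fields.get("ROLE_COD", "").strip().upper()
            role = _ROLE_MAP.get(role_code)
            if role is None:
                log.warning("ISR %s: unknown drug role %r, treating as concomitant", isr, role_code)
                n_warn += 1
                role = DrugRole.CONCOMITANT
            name = dr.fields.get("DRUGNAME", "")
            if name:
                drugs.append(DrugMention(verbatim_name=name, role=role))
        if not drugs:
            excluded[isr] = "no drugs"
            continue

        reactions = [r.fields.get("PT", "") for r in reac_rows if r.fields.get("PT", "")]
        if not reactions:
            excluded[isr] = "no reactions"
            continue

        outcomes = set()
        for orow in tables.get(TableName.OUTC, []):
            code = orow.fields.get("OUTC_COD", "").strip().upper()
            if not code:
                continue
            if code in _OUTC_MAP:
                outcomes.add(_OUTC_MAP[code])
            else:
                log.warning("ISR %s: unknown outcome code %r, mapped to OTHER", isr, code)
                n_warn += 1
                outcomes.add(Outcome.OTHER)

        sources = frozenset(
            r.fields.get("RPSR_COD", "").strip()
            for r in tables.get(TableName.RPSR, [])
            if r.fields.get("RPSR_COD", "").strip()
        )

        cases.append(
            CaseReport(
                isr_id=isr,
                case_id=case_id,
                receipt_date=receipt,
                age=age,
                sex=sex,
                reporter_occupation=occupation,
                drugs=drugs,
                reactions=reactions,
                outcomes=frozenset(outcomes),
                report_sources=sources,
                date_flagged=date_flagged,
            )
        )
    return AssembleResult(cases=cases, excluded=excluded, n_warnings=n_warn)


#: Study window for the statin analysis: FDA receipt dates 2005-07-01..2011-03-31.
DEFAULT_WINDOW = (date(2005, 7, 1), date(2011, 3, 31))


def filter_date_window(
    cases: Sequence[CaseReport],
    start: date = DEFAULT_WINDOW[0],
    end: date = DEFAULT_WINDOW[1],
) -> tuple[list[CaseReport], int]:
    """Keep reports received inside [start, end].

    Reports with an unparseable or missing receipt date are kept (they are
    already flagged on the record) — dropping them silently would bias
    counts; returns (kept, n_outside_window).
    """
    kept, dropped = [], 0
    for c in cases:
        if c.receipt_date is None:
            kept.append(c)
        elif start <= c.receipt_date <= end:
            kept.append(c)
        else:
            dropped += 1
    return kept, dropped


def write_table(table: pd.DataFrame, path: Path | str) -> None:
    """Write a result table as RFC-4180 CSV with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path: Path | str) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path)
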