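"""One-command orchestration: read → normalize → dedup → categorize → rank.

Every stage's output is materialized in the run directory so the analysis
is auditable end to end: the consolidation report, dedup decision log, all
risk tables, stratifications, and a JSON manifest recording the config
hash, row-count conservation at each stage, and a digest of every output
file.  Reruns with identical inputs and config produce identical outputs
and identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as aio
from .categories import EventCategory, load_categories
from .dedup import decisions_frame, dedup_heuristic, dedup_versions
from .metrics import (
    PrescriptionTable,
    ROLE_SCOPE_PRIMARY,
    combined_risk,
    format_risk_table,
    risk_table,
    stratify,
    yearly_trend,
)
from .normalize import SynonymDictionary, annotate_cases

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: Path
    dictionary_path: Path
    category_path: Path
    prescription_path: Path
    output_dir: Path
    drugs: Optional[list[str]] = None  # default: dictionary ∩ prescription table
    window: Optional[tuple[date, date]] = aio.DEFAULT_WINDOW
    max_distance: int = 1
    dedup_window_days: int = 30
    enable_heuristic_dedup: bool = True
    include_concomitant: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("input_dir", "dictionary_path", "category_path", "prescription_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        if d.get("window"):
            d["window"] = [x.isoformat() for x in self.window]
        return d


def discover_quarters(input_dir: Path | str) -> dict[str, dict[aio.TableName, Path]]:
    """Find per-quarter table files named ``{prefix}_{TABLE}.txt``."""
    input_dir = Path(input_dir)
    quarters: dict[str, dict[aio.TableName, Path]] = {}
    for demo in sorted(input_dir.glob("*_DEMO.txt")):
        prefix = demo.name[: -len("_DEMO.txt")]
        quarters[prefix] = {
            t: input_dir / f"{prefix}_{t.value}.txt"
            for t in aio.TableName
            if (input_dir / f"{prefix}_{t.value}.txt").exists()
        }
    if not quarters:
        raise FileNotFoundError(f"no quarterly files (*_DEMO.txt) under {input_dir}")
    return quarters


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class Manifest:
    config: dict
    config_hash: str
    counts: dict
    conservation_ok: bool
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run(config: RunConfig) -> Manifest:
    """Execute the full pipeline; see module docstring for the outputs."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: read
    quarters = discover_quarters(config.input_dir)
    rows, rejects = [], []
    for prefix in sorted(quarters):
        rr = aio.read_quarter(quarters[prefix])
        rows.extend(rr.rows)
        rejects.extend(rr.rejects)

    # stage 2: assemble + window
    assembled = aio.assemble_cases(rows)
    cases = assembled.cases
    if config.window is not None:
        cases, n_outside = aio.filter_date_window(cases, *config.window)
    else:
        n_outside = 0

    # stage 3: name consolidation
    dictionary = SynonymDictionary.from_csv(config.dictionary_path)
    cases, consolidation = annotate_cases(cases, dictionary, config.max_distance)
    aio.write_table(consolidation, out / "consolidation_report.csv")

    # stage 4: dedup
    n_before_dedup = len(cases)
    cases, version_decisions = dedup_versions(cases)
    if config.enable_heuristic_dedup:
        cases, heur_decisions = dedup_heuristic(cases, config.dedup_window_days)
    else:
        heur_decisions = []
    decisions = list(version_decisions) + list(heur_decisions)
    aio.write_table(decisions_frame(decisions), out / "dedup_decisions.csv")
    n_dropped = sum(len(d.dropped_isrs) for d in decisions)

    # stage 5: categories + denominators
    categories = load_categories(config.category_path)
    pr_table = PrescriptionTable.from_csv(config.prescription_path)
    drugs = config.drugs or sorted(set(pr_table.pr) & dictionary.canonical_drugs)
    if not drugs:
        raise ValueError("no drugs shared between dictionary and prescription table")

    # stage 6: tables
    for cat in categories:
        df = risk_table(cases, drugs, cat, pr_table, config.include_concomitant)
        aio.write_table(format_risk_table(df), out / f"risk_{_slug(cat.name)}.csv")

    combined = combined_risk(cases, drugs, categories, pr_table, ROLE_SCOPE_PRIMARY)
    aio.write_table(
        pd.DataFrame(
            {"drug": list(combined), "combined_percent_of_max": list(combined.values())}
        ),
        out / "combined_risk.csv",
    )

    trend_rows = []
    for cat in categories:
        for d in drugs:
            for year, n in yearly_trend(cases, d, cat).items():
                trend_rows.append({"category": cat.name, "drug": d, "year": year, "count": n})
    aio.write_table(
        pd.DataFrame(trend_rows, columns=["category", "drug", "year", "count"]),
        out / "yearly_trends.csv",
    )

    strat_rows = []
    for axis in ("OUTCOME", "REPORTER"):
        for cat in categories:
            for d in drugs:
                df = stratify(cases, d, cat, axis)
                for rec in df.to_dict("records"):
                    strat_rows.append({"axis": axis, "category": cat.name, "drug": d, **rec})
    aio.write_table(
        pd.DataFrame(strat_rows, columns=["axis", "category", "drug", "stratum", "count", "percent"]),
        out / "stratified.csv",
    )

    # manifest
    counts = {
        "rows_read": len(rows),
        "rows_rejected": len(rejects),
        "cases_assembled": len(assembled.cases),
        "cases_excluded": assembled.n_excluded,
        "outside_window": n_outside,
        "before_dedup": n_before_dedup,
        "dropped_by_dedup": n_dropped,
        "final_cases": len(cases),
    }
    conservation_ok = (
        len(assembled.cases) + assembled.n_excluded
        == len({r.isr_id for r in rows})
    ) and (n_before_dedup == len(cases) + n_dropped)
    cfg = config.to_jsonable()
    manifest = Manifest(
        config=cfg,
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        counts=counts,
        conservation_ok=conservation_ok,
    )
    for p in sorted(out.glob("*.csv")):
        manifest.outputs[p.name] = _sha256(p)
    (out / "manifest.json").write_text(manifest.to_json())
    if not conservation_ok:
        log.error("row-count conservation violated: %s", counts)
    return manifest


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name.lower()).strip("_")
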