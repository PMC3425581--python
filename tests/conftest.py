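from __future__ import annotations

from datetime import date
from pathlib import Path

import pytest
from hypothesis import settings

from aerspipe.categories import make_category
from aerspipe.io import DEFAULT_COLUMNS, TableName
from aerspipe.normalize import SynonymDictionary

settings.register_profile("default", derandomize=True, max_examples=200)
settings.load_profile("default")


def write_quarter(
    directory: Path,
    demo: list[list[str]] | None = None,
    drug: list[list[str]] | None = None,
    reac: list[list[str]] | None = None,
    outc: list[list[str]] | None = None,
    rpsr: list[list[str]] | None = None,
    prefix: str = "2006Q1",
) -> dict[TableName, Path]:
    """Write raw quarterly table files from row lists; returns per-table paths."""
    directory.mkdir(parents=True, exist_ok=True)
    tables = {
        TableName.DEMO: demo or [],
        TableName.DRUG: drug or [],
        TableName.REAC: reac or [],
        TableName.OUTC: outc or [],
        TableName.RPSR: rpsr or [],
    }
    paths = {}
    for table, rows in tables.items():
        lines = ["$".join(DEFAULT_COLUMNS[table])]
        lines += ["$".join(r) for r in rows]
        path = directory / f"{prefix}_{table.value}.txt"
        path.write_text("\n".join(lines) + "\n")
        paths[table] = path
    return paths


def demo_row(isr: str, case: str | None = None, fda_dt: str = "20060115",
             age: str = "60", sex: str = "F", occ: str = "MD") -> list[str]:
    return [isr, case or f"C{isr}", fda_dt, age, sex, occ]


@pytest.fixture
def statin_dictionary() -> SynonymDictionary:
    return SynonymDictionary.from_entries(
        {
            "atorvastatin": ["lipitor", "atorvastatin calcium"],
            "simvastatin": ["zocor"],
            "rosuvastatin": ["crestor"],
            "pravastatin": ["pravachol"],
            "lovastatin": ["mevacor"],
            "fluvastatin": ["lescol"],
        }
    )


@pytest.fixture
def myalgia_category():
    return make_category("Myalgia", ["myalgia"])


@pytest.fixture
def window_2006():
    return (date(2006, 1, 1), date(2006, 12, 31))
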