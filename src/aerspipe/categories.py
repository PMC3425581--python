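"""Adverse-event categories: named reaction-term search lists.

A category is a set of coded reaction-term strings (MedDRA preferred-term
style); a case belongs to a category if any of its reactions matches any
category term.  Matching is exact-term by default — reactions in AERS-style
extracts are coded terms — with a substring mode available for deliberately
broad categories.  A case counts once per category no matter how many of
its reactions match.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .io import CaseReport
from .util import collapse_ws


class MatchMode(str, enum.Enum):
    EXACT_TERM = "EXACT_TERM"
    SUBSTRING = "SUBSTRING"


class CategoryError(ValueError):
    pass


@dataclass(frozen=True)
class EventCategory:
    name: str
    terms: frozenset[str]
    match_mode: MatchMode = MatchMode.EXACT_TERM

    def __post_init__(self) -> None:
        if not self.terms:
            raise CategoryError(f"category {self.name!r} has no terms")


def make_category(
    name: str, terms: Sequence[str], match_mode: MatchMode = MatchMode.EXACT_TERM
) -> EventCategory:
    """Build a category with normalized, de-duplicated terms."""
    norm = frozenset(collapse_ws(t) for t in terms if collapse_ws(t))
    return EventCategory(name=name, terms=norm, match_mode=match_mode)


def load_categories(path: Path | str) -> list[EventCategory]:
    """Load category definitions from YAML or CSV.

    YAML: ``{name: [terms]}`` or ``{name: {terms: [...], mode: ...}}``.
    CSV: columns ``category,term[,mode]``, one term per row.
    Categories may share terms (they are analysed independently); a
    category with no terms is a fatal configuration error.
    """
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        spec = yaml.safe_load(path.read_text())
        if not isinstance(spec, dict) or not spec:
            raise CategoryError(f"no categories in {path}")
        out = []
        for name, body in spec.items():
            if isinstance(body, dict):
                terms = body.get("terms", [])
                mode = MatchMode(body.get("mode", "EXACT_TERM"))
            else:
                terms, mode = body, MatchMode.EXACT_TERM
            if not terms:
                raise CategoryError(f"category {name!r} has no terms")
            out.append(make_category(str(name), [str(t) for t in terms], mode))
        return out
    # CSV
    grouped: dict[str, tuple[list[str], MatchMode]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "category" not in reader.fieldnames:
            raise CategoryError(f"expected 'category,term[,mode]' header in {path}")
        for row in reader:
            name = row["category"]
            mode = MatchMode(row.get("mode") or "EXACT_TERM")
            grouped.setdefault(name, ([], mode))[0].append(row["term"])
    if not grouped:
        raise CategoryError(f"no categories in {path}")
    return [make_category(n, terms, mode) for n, (terms, mode) in grouped.items()]


def default_categories() -> list[EventCategory]:
    """The shipped statin muscle/tendon category set."""
    with resources.as_file(resources.files("aerspipe.data") / "categories.yml") as p:
        return load_categories(p)


def case_matches(case: CaseReport, category: EventCategory) -> bool:
    """True iff at least one reaction on the case matches the category."""
    reactions = (collapse_ws(r) for r in case.reactions)
    if category.match_mode is MatchMode.EXACT_TERM:
        return any(r in category.terms for r in reactions)
    return any(t in r for r in reactions for t in category.terms)
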