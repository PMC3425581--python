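"""Drug-name consolidation.

Spontaneous reports carry free-text drug names: brand and generic names,
foreign designations, misspellings, salt forms, and dosage descriptions
("LIPITOR 10 MG TABLET").  Every variant must be consolidated under one
canonical drug before counting, or per-drug report counts fragment across
spellings.  Consolidation is dictionary-driven (a curated synonym table),
with optional bounded-edit-distance fuzzy matching as a safety net for
misspellings the dictionary misses.  Fuzzy matching never overrides an
exact dictionary hit, and a tie between two canonical drugs at the same
distance is never guessed — it yields no match, with a logged ambiguity.
"""

from __future__ import annotations

import csv
import enum
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pandas as pd

from .io import CaseReport
from .util import collapse_ws

log = logging.getLogger(__name__)

#: Dosage/strength/form tokens stripped from the end of a name.
SUFFIX_TOKENS = frozenset(
    {"mg", "mcg", "g", "ml", "tab", "tablet", "tabs", "cap", "capsule",
     "caps", "hcl", "er", "xl", "sr"}
)

_BRACKETED = re.compile(r"\([^)]*\)|\[[^\]]*\]|\{[^}]*\}")
_PUNCT = re.compile(r"[^\w\s]|_")
_NUM = re.compile(r"^\d+(\.\d+)?$")
_NUM_UNIT = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml)$")


def normalize_name(raw: str) -> str:
    """Canonicalise one verbatim drug-name string.

    Case-folds, drops bracketed qualifiers, turns punctuation into spaces,
    collapses whitespace, then strips trailing dosage/strength/form tokens
    (bare numbers, number+unit, and the suffix vocabulary).  Idempotent.
    """
    s = _BRACKETED.sub(" ", raw.casefold())
    s = _PUNCT.sub(" ", s)
    tokens = collapse_ws(s).split()
    while tokens:
        t = tokens[-1]
        if t in SUFFIX_TOKENS or _NUM.match(t) or _NUM_UNIT.match(t):
            tokens.pop()
        else:
            break
    return " ".join(tokens)


class MatchMethod(str, enum.Enum):
    EXACT = "EXACT"
    FUZZY = "FUZZY"
    NONE = "NONE"


@dataclass(frozen=True)
class MatchResult:
    canonical_drug: Optional[str]
    method: MatchMethod
    distance: Optional[int]  # 0 for EXACT, edit distance for FUZZY, None for NONE
    matched_variant: Optional[str]


class DictionaryError(ValueError):
    """A variant string maps to more than one canonical drug."""


@dataclass
class SynonymDictionary:
    """Canonical drug ↔ variant-string mapping, stored normalized.

    Each canonical name is implicitly its own variant.  Loading fails fast
    if any variant is claimed by two canonical drugs.
    """

    variant_to_canonical: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)  # variant -> curated|generated

    def __post_init__(self) -> None:
        for v in self.variant_to_canonical:
            if v != normalize_name(v):
                raise DictionaryError(f"variant {v!r} is not in normalized form")

    @property
    def canonical_drugs(self) -> frozenset[str]:
        return frozenset(self.variant_to_canonical.values())

    @property
    def variants(self) -> list[str]:
        return sorted(self.variant_to_canonical)

    @classmethod
    def from_entries(
        cls,
        entries: Mapping[str, Iterable[str]],
        provenance: str = "curated",
    ) -> "SynonymDictionary":
        v2c: dict[str, str] = {}
        prov: dict[str, str] = {}
        for canonical, variants in entries.items():
            canon_norm = normalize_name(canonical)
            for variant in list(variants) + [canonical]:
                v = normalize_name(variant)
                if not v:
                    continue
                if v in v2c and v2c[v] != canon_norm:
                    raise DictionaryError(
                        f"variant {variant!r} maps to both {v2c[v]!r} and {canon_norm!r}"
                    )
                v2c[v] = canon_norm
                prov[v] = provenance
        return cls(variant_to_canonical=v2c, provenance=prov)

    @classmethod
    def from_csv(cls, path: Path | str) -> "SynonymDictionary":
        """Load a two-column (canonical, variant) CSV."""
        entries: dict[str, list[str]] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if [h.strip().lower() for h in header[:2]] != ["canonical", "variant"]:
                raise DictionaryError(
                    f"expected header 'canonical,variant' in {path}, got {header!r}"
                )
            for row in reader:
                if len(row) < 2:
                    continue
                entries.setdefault(row[0], []).append(row[1])
        return cls.from_entries(entries)


def levenshtein(a: str, b: str, limit: Optional[int] = None) -> int:
    """Levenshtein edit distance (edlib NW alignment); -1 if beyond limit."""
    k = -1 if limit is None else limit
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def match_drug(
    raw: str, dictionary: SynonymDictionary, max_distance: int = 1
) -> MatchResult:
    """Resolve one verbatim name against the synonym dictionary.

    Exact (post-normalization) dictionary hits win outright.  Otherwise the
    nearest variant by Levenshtein distance wins if it is within
    ``max_distance`` and the canonical drug at that distance is unique;
    ties across canonical drugs return no match.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    name = normalize_name(raw)
    if not name:
        return MatchResult(None, MatchMethod.NONE, None, None)
    hit = dictionary.variant_to_canonical.get(name)
    if hit is not None:
        return MatchResult(hit, MatchMethod.EXACT, 0, name)
    if max_distance == 0:
        return MatchResult(None, MatchMethod.NONE, None, None)

    best_d: Optional[int] = None
    best: list[tuple[str, str]] = []  # (variant, canonical) at best_d
    for variant in dictionary.variants:
        d = levenshtein(name, variant, limit=max_distance)
        if d < 0:
            continue
        if best_d is None or d < best_d:
            best_d, best = d, [(variant, dictionary.variant_to_canonical[variant])]
        elif d == best_d:
            best.append((variant, dictionary.variant_to_canonical[variant]))
    if best_d is None:
        return MatchResult(None, MatchMethod.NONE, None, None)
    canonicals = {c for _, c in best}
    if len(canonicals) > 1:
        log.warning(
            "ambiguous fuzzy match for %r at distance %d: %s", raw, best_d, sorted(canonicals)
        )
        return MatchResult(None, MatchMethod.NONE, None, None)
    variant, canonical = best[0]
    return MatchResult(canonical, MatchMethod.FUZZY, best_d, variant)


def annotate_cases(
    cases: Sequence[CaseReport],
    dictionary: SynonymDictionary,
    max_distance: int = 1,
) -> tuple[list[CaseReport], pd.DataFrame]:
    """Fill ``canonical_drug`` on every drug mention.

    Returns the annotated cases and a consolidation report: one row per
    distinct verbatim string, with the canonical drug it consolidated to
    (empty for unmatched), the match method, and the mention count.
    """
    cache: dict[str, MatchResult] = {}
    counts: dict[str, int] = {}
    annotated: list[CaseReport] = []
    for case in cases:
        mentions = []
        for m in case.drugs:
            res = cache.get(m.verbatim_name)
            if res is None:
                res = match_drug(m.verbatim_name, dictionary, max_distance)
                cache[m.verbatim_name] = res
            counts[m.verbatim_name] = counts.get(m.verbatim_name, 0) + 1
            mentions.append(replace(m, canonical_drug=res.canonical_drug))
        annotated.append(case.with_drugs(mentions))
    report = pd.DataFrame(
        [
            {
                "canonical": cache[v].canonical_drug or "",
                "variant": v,
                "count": counts[v],
                "method": cache[v].method.value,
            }
            for v in sorted(cache)
        ],
        columns=["canonical", "variant", "count", "method"],
    ).sort_values(["canonical", "variant"], ignore_index=True)
    return annotated, report
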