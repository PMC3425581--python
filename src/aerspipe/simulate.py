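"""Synthetic AERS-style report generator with ground truth.

No public extract ships with this package, so every pipeline stage is
validated against simulated quarterly files whose generating process is
fully known.  Reports are drawn so that the expected report count for a
(drug, category) cell is proportional to prescribing weight × per-category
reporting rate (the same count/denominator structure the risk metrics
assume).  On top of the clean signal the generator injects the pathologies
the pipeline exists to handle: name variants (bounded random edits sparing
the first three characters, plus dosage-suffix decoration), follow-up
report versions sharing a case key, and near-exact duplicate submissions
under fresh case keys.  Every emitted report has exactly one ground-truth
record, and the same seed reproduces the output files byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .categories import EventCategory, case_matches
from .dedup import DedupDecision, DropReason
from .io import CaseReport, TableName

log = logging.getLogger(__name__)

#: Background (non-category) reaction-term pool; disjoint from the shipped
#: muscle/tendon category terms so matches are unambiguous.
DEFAULT_BACKGROUND_TERMS = (
    "nausea", "headache", "dizziness", "fatigue", "rash", "diarrhoea",
    "vomiting", "insomnia", "pruritus", "dyspnoea", "constipation",
    "abdominal pain", "cough", "oedema peripheral", "anxiety", "pyrexia",
)

#: Non-study drugs used for concomitant mentions and swapped-role suspects.
COMEDICATION_POOL = (
    "aspirin", "metformin", "lisinopril", "amlodipine", "omeprazole",
    "levothyroxine", "clopidogrel", "metoprolol",
)

DEFAULT_REPORTER_MIX = {
    "PHYSICIAN": 0.32, "PHARMACIST": 0.10, "OTHER_HEALTH_PROFESSIONAL": 0.16,
    "CONSUMER": 0.38, "LAWYER": 0.02, "UNKNOWN": 0.02,
}

#: Per-outcome marginal probabilities (outcomes are not exclusive).
DEFAULT_OUTCOME_MIX = {
    "HOSPITALIZATION": 0.22, "DEATH": 0.03, "LIFE_THREATENING": 0.04,
    "DISABILITY": 0.05, "REQUIRED_INTERVENTION": 0.02, "OTHER": 0.30,
}

_OCC_CODE = {
    "PHYSICIAN": "MD", "PHARMACIST": "PH", "OTHER_HEALTH_PROFESSIONAL": "OT",
    "CONSUMER": "CN", "LAWYER": "LW", "UNKNOWN": "",
}
_OUTC_CODE = {
    "DEATH": "DE", "LIFE_THREATENING": "LT", "HOSPITALIZATION": "HO",
    "DISABILITY": "DS", "CONGENITAL_ANOMALY": "CA",
    "REQUIRED_INTERVENTION": "RI", "OTHER": "OT",
}
_RPSR_CODES = ("HP", "CSM", "FGN", "LIT", "OTH")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DrugSpec:
    """One simulated drug: market size and per-category reporting rates."""

    name: str
    prescribing_weight: float  # proportional to NRx
    category_rates: dict[str, float]  # category name -> reports per 1e6 prescriptions


@dataclass
class SimulationConfig:
    drugs: list[DrugSpec]
    categories: list[EventCategory]
    n_reports: int = 1000
    background_terms: tuple[str, ...] = DEFAULT_BACKGROUND_TERMS
    duplicate_rate: float = 0.0
    followup_rate: float = 0.0
    name_corruption: tuple[float, int] = (0.0, 1)  # (variant probability, max edits)
    primary_role_prob: float = 1.0  # else the drug is secondary suspect
    concomitant_rate: float = 0.0
    reporter_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REPORTER_MIX))
    outcome_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MIX))
    date_range: tuple[date, date] = (date(2005, 7, 1), date(2011, 3, 31))
    seed: int = 0

    def validate(self) -> None:
        if not self.drugs:
            raise ConfigError("drugs: at least one drug required")
        if self.n_reports <= 0:
            raise ConfigError("n_reports: must be > 0")
        for name, rate in (
            ("duplicate_rate", self.duplicate_rate),
            ("followup_rate", self.followup_rate),
            ("primary_role_prob", self.primary_role_prob),
            ("concomitant_rate", self.concomitant_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1]")
        p_corrupt, max_edits = self.name_corruption
        if not 0.0 <= p_corrupt <= 1.0 or max_edits < 0:
            raise ConfigError("name_corruption: probability in [0,1], max edits >= 0")
        if abs(sum(self.reporter_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("reporter_mix: probabilities must sum to 1")
        if any(p < 0 or p > 1 for p in self.outcome_mix.values()):
            raise ConfigError("outcome_mix: per-outcome probabilities must be in [0, 1]")
        cat_names = {c.name for c in self.categories}
        for d in self.drugs:
            if d.prescribing_weight <= 0:
                raise ConfigError(f"drugs[{d.name}].prescribing_weight: must be > 0")
            unknown = set(d.category_rates) - cat_names
            if unknown:
                raise ConfigError(f"drugs[{d.name}].category_rates: unknown categories {unknown}")
            if any(r < 0 for r in d.category_rates.values()):
                raise ConfigError(f"drugs[{d.name}].category_rates: rates must be >= 0")
            if sum(d.category_rates.values()) / 1e6 > 1.0:
                raise ConfigError(
                    f"drugs[{d.name}].category_rates: total exceeds 1e6 per 1e6 prescriptions"
                )
        if self.date_range[0] > self.date_range[1]:
            raise ConfigError("date_range: start after end")

    def nrx(self, scale: int = 1_000_000) -> dict[str, int]:
        """Prescription counts consistent with the configured weights."""
        return {d.name: int(round(d.prescribing_weight * scale)) for d in self.drugs}


@dataclass
class _Report:
    isr: str
    case_id: str
    receipt: date
    age: int
    sex: str
    occupation: str
    drug_verbatim: str
    drug_role: str
    extra_drugs: list[tuple[str, str]]  # (verbatim, role code)
    reactions: list[str]
    outcomes: list[str]
    source: str
    # truth labels
    true_drug: str
    true_category: str
    is_duplicate_of: str = ""
    is_followup_of: str = ""


@dataclass
class SimulationOutput:
    out_dir: Path
    quarters: dict[str, dict[TableName, Path]]  # "2006Q3" -> per-table paths
    truth: pd.DataFrame
    truth_path: Path
    config: SimulationConfig


def config_from_yaml(path: Path | str) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML.

    Schema: top-level SimulationConfig field names; ``categories`` maps
    name → term list; ``drugs`` is a list of {name, prescribing_weight,
    category_rates}; ``date_range`` is a pair of ISO dates.
    """
    import yaml

    from .categories import make_category

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"not a mapping: {path}")
    kwargs = dict(raw)
    kwargs["categories"] = [
        make_category(str(n), [str(t) for t in terms])
        for n, terms in raw.get("categories", {}).items()
    ]
    kwargs["drugs"] = [
        DrugSpec(
            name=d["name"],
            prescribing_weight=float(d["prescribing_weight"]),
            category_rates={str(k): float(v) for k, v in d.get("category_rates", {}).items()},
        )
        for d in raw.get("drugs", [])
    ]
    if "name_corruption" in raw:
        p, k = raw["name_corruption"]
        kwargs["name_corruption"] = (float(p), int(k))
    if "date_range" in raw:
        a, b = raw["date_range"]
        kwargs["date_range"] = (date.fromisoformat(str(a)), date.fromisoformat(str(b)))
    if "background_terms" in raw:
        kwargs["background_terms"] = tuple(raw["background_terms"])
    config = SimulationConfig(**kwargs)
    config.validate()
    return config


def _corrupt_name(name: str, rng: np.random.Generator, max_edits: int) -> str:
    """Apply 1..max_edits random edits, never touching the first 3 characters."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    s = list(name)
    n_edits = int(rng.integers(1, max_edits + 1)) if max_edits >= 1 else 0
    for _ in range(n_edits):
        if len(s) <= 3:
            break
        op = int(rng.integers(0, 3))
        if op == 0:  # substitute
            pos = int(rng.integers(3, len(s)))
            choices = letters.replace(s[pos], "") if s[pos] in letters else letters
            s[pos] = choices[int(rng.integers(0, len(choices)))]
        elif op == 1:  # delete
            pos = int(rng.integers(3, len(s)))
            del s[pos]
        else:  # insert
            pos = int(rng.integers(3, len(s) + 1))
            s.insert(pos, letters[int(rng.integers(0, 26))])
    return "".join(s)


def _choice(rng: np.random.Generator, items: Sequence[str], probs: Sequence[float]) -> str:
    return items[int(rng.choice(len(items), p=np.asarray(probs) / sum(probs)))]


def generate(config: SimulationConfig, out_dir: Path | str) -> SimulationOutput:
    """Generate quarterly extract files plus a ground-truth table.

    Files follow the default dialect ($-delimited, header row) and are
    named ``{YYYY}Q{q}_{TABLE}.txt``; the truth table is written as
    ``ground_truth.csv`` alongside them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    weights = np.array([d.prescribing_weight for d in config.drugs], dtype=float)
    weights /= weights.sum()
    cats = list(config.categories)
    cat_terms = {c.name: sorted(c.terms) for c in cats}
    # per-drug category probabilities; remainder is background noise
    cat_p = []
    for d in config.drugs:
        p = np.array([d.category_rates.get(c.name, 0.0) / 1e6 for c in cats])
        cat_p.append(np.append(p, 1.0 - p.sum()))

    start, end = config.date_range
    n_days = (end - start).days
    occs = sorted(config.reporter_mix)
    occ_p = [config.reporter_mix[o] for o in occs]
    outcomes_sorted = sorted(config.outcome_mix)
    p_corrupt, max_edits = config.name_corruption

    next_id = [1_000_000]

    def new_isr() -> str:
        next_id[0] += 1
        return str(next_id[0])

    def draw_background(k: int) -> list[str]:
        idx = rng.choice(len(config.background_terms), size=min(k, len(config.background_terms)),
                         replace=False) if k else []
        return [config.background_terms[int(i)] for i in idx]

    def emit_name(canonical: str) -> str:
        name = canonical
        if p_corrupt > 0 and rng.random() < p_corrupt:
            name = _corrupt_name(name, rng, max_edits)
            if rng.random() < 0.5:
                name = f"{name} {int(rng.integers(1, 9)) * 10} mg tablet"
        return name.upper()

    reports: list[_Report] = []
    for _ in range(config.n_reports):
        di = int(rng.choice(len(config.drugs), p=weights))
        drug = config.drugs[di]
        ci = int(rng.choice(len(cats) + 1, p=cat_p[di]))
        if ci < len(cats):
            category = cats[ci].name
            terms = cat_terms[category]
            signal_term = terms[int(rng.integers(0, len(terms)))]
            reactions = [signal_term] + draw_background(int(rng.poisson(1.0)))
        else:
            category = ""
            reactions = draw_background(1 + int(rng.poisson(1.0)))
            if not reactions:
                reactions = [config.background_terms[0]]

        role = "PS" if rng.random() < config.primary_role_prob else "SS"
        extra: list[tuple[str, str]] = []
        if role == "SS":
            other = COMEDICATION_POOL[int(rng.integers(0, len(COMEDICATION_POOL)))]
            extra.append((other.upper(), "PS"))
        if config.concomitant_rate > 0 and rng.random() < config.concomitant_rate:
            other = COMEDICATION_POOL[int(rng.integers(0, len(COMEDICATION_POOL)))]
            extra.append((other.upper(), "C"))

        isr = new_isr()
        reports.append(
            _Report(
                isr=isr,
                case_id=f"C{isr}",
                receipt=start + timedelta(days=int(rng.integers(0, n_days + 1))),
                age=int(rng.integers(18, 100)),
                sex="M" if rng.random() < 0.5 else "F",
                occupation=_choice(rng, occs, occ_p),
                drug_verbatim=emit_name(drug.name),
                drug_role=role,
                extra_drugs=extra,
                reactions=reactions,
                outcomes=[o for o in outcomes_sorted if rng.random() < config.outcome_mix[o]],
                source=_RPSR_CODES[int(rng.integers(0, len(_RPSR_CODES)))],
                true_drug=drug.name,
                true_category=category,
            )
        )

    # follow-up versions: same case key, later receipt, same content
    followups: list[_Report] = []
    for base in reports:
        if config.followup_rate > 0 and rng.random() < config.followup_rate:
            fu_date = min(base.receipt + timedelta(days=int(rng.integers(35, 200))), end)
            followups.append(
                _Report(
                    isr=new_isr(), case_id=base.case_id, receipt=fu_date,
                    age=base.age, sex=base.sex, occupation=base.occupation,
                    drug_verbatim=base.drug_verbatim, drug_role=base.drug_role,
                    extra_drugs=list(base.extra_drugs), reactions=list(base.reactions),
                    outcomes=list(base.outcomes), source=base.source,
                    true_drug=base.true_drug, true_category=base.true_category,
                    is_followup_of=base.isr,
                )
            )
    # duplicate submissions: fresh case key, near-identical fields
    duplicates: list[_Report] = []
    for base in reports:
        if config.duplicate_rate > 0 and rng.random() < config.duplicate_rate:
            isr = new_isr()
            duplicates.append(
                _Report(
                    isr=isr, case_id=f"C{isr}",
                    receipt=min(base.receipt + timedelta(days=int(rng.integers(0, 6))), end),
                    age=base.age, sex=base.sex, occupation=base.occupation,
                    drug_verbatim=base.drug_verbatim, drug_role=base.drug_role,
                    extra_drugs=list(base.extra_drugs), reactions=list(base.reactions),
                    outcomes=list(base.outcomes), source=base.source,
                    true_drug=base.true_drug, true_category=base.true_category,
                    is_duplicate_of=base.isr,
                )
            )

    everything = sorted(reports + followups + duplicates, key=lambda r: r.isr)
    quarters = _write_quarters(everything, out_dir)

    truth = pd.DataFrame(
        [
            {
                "isr": r.isr, "case_id": r.case_id, "drug": r.true_drug,
                "role": r.drug_role, "category": r.true_category,
                "is_duplicate_of": r.is_duplicate_of,
                "is_followup_of": r.is_followup_of,
                "injected_variant": r.drug_verbatim,
                "receipt_date": r.receipt.isoformat(),
            }
            for r in everything
        ]
    )
    truth_path = out_dir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    return SimulationOutput(
        out_dir=out_dir, quarters=quarters, truth=truth, truth_path=truth_path, config=config
    )


def _write_quarters(reports: Sequence[_Report], out_dir: Path) -> dict[str, dict[TableName, Path]]:
    from .io import DEFAULT_COLUMNS

    by_q: dict[str, list[_Report]] = {}
    for r in reports:
        q = f"{r.receipt.year}Q{(r.receipt.month - 1) // 3 + 1}"
        by_q.setdefault(q, []).append(r)

    quarters: dict[str, dict[TableName, Path]] = {}
    for q in sorted(by_q):
        lines: dict[TableName, list[str]] = {t: ["$".join(DEFAULT_COLUMNS[t])] for t in TableName}
        for r in sorted(by_q[q], key=lambda r: r.isr):
            fda_dt = r.receipt.strftime("%Y%m%d")
            lines[TableName.DEMO].append(
                "$".join([r.isr, r.case_id, fda_dt, str(r.age), r.sex, _OCC_CODE[r.occupation]])
            )
            mentions = [(r.drug_verbatim, r.drug_role)] + r.extra_drugs
            for seq, (name, role) in enumerate(mentions, start=1):
                lines[TableName.DRUG].append("$".join([r.isr, str(seq), role, name]))
            for pt in r.reactions:
                lines[TableName.REAC].append("$".join([r.isr, pt]))
            for o in r.outcomes:
                lines[TableName.OUTC].append("$".join([r.isr, _OUTC_CODE[o]]))
            lines[TableName.RPSR].append("$".join([r.isr, r.source]))
        quarters[q] = {}
        for t in TableName:
            path = out_dir / f"{q}_{t.value}.txt"
            path.write_text("\n".join(lines[t]) + "\n")
            quarters[q][t] = path
    return quarters


@dataclass
class RecoveryReport:
    """Exact-count comparison of pipeline output against ground truth."""

    n_truth_reports: int
    n_survivors: int
    # heuristic duplicate detection
    dup_injected: int
    dup_detected: int
    dup_true_positive: int
    # follow-up resolution: cases with >1 version that kept exactly one report
    multiversion_cases: int
    multiversion_resolved: int
    # name consolidation over surviving reports' study-drug mention
    consolidation_total: int
    consolidation_correct: int
    consolidation_wrong: int  # assigned, but to the wrong canonical drug
    # category matching over surviving reports
    category_total: int
    category_correct: int
    category_false_positive: int

    @property
    def dedup_recall(self) -> float:
        return 1.0 if self.dup_injected == 0 else self.dup_true_positive / self.dup_injected

    @property
    def dedup_precision(self) -> float:
        return 1.0 if self.dup_detected == 0 else self.dup_true_positive / self.dup_detected

    @property
    def consolidation_recall(self) -> float:
        if self.consolidation_total == 0:
            return 1.0
        return self.consolidation_correct / self.consolidation_total

    @property
    def consolidation_precision(self) -> float:
        assigned = self.consolidation_correct + self.consolidation_wrong
        return 1.0 if assigned == 0 else self.consolidation_correct / assigned

    @property
    def category_recall(self) -> float:
        return 1.0 if self.category_total == 0 else self.category_correct / self.category_total


def truth_compare(
    survivors: Sequence[CaseReport],
    decisions: Sequence[DedupDecision],
    truth: pd.DataFrame,
    categories: Sequence[EventCategory],
) -> RecoveryReport:
    """Score dedup, consolidation, and category matching against truth.

    ``survivors`` must be the annotated post-dedup cases derived from the
    same :func:`generate` call that produced ``truth``; unknown ISRs are a
    fatal mismatch.
    """
    t = truth.fillna("")
    truth_by_isr = {str(r.isr): r for r in t.itertuples()}
    unknown = [c.isr_id for c in survivors if c.isr_id not in truth_by_isr]
    if unknown:
        raise ValueError(f"cases not from this simulation run: {unknown[:5]}")

    injected_dups = {str(r.isr) for r in t.itertuples() if r.is_duplicate_of}
    detected = {
        isr
        for d in decisions
        if d.reason is DropReason.HEURISTIC_DUPLICATE
        for isr in d.dropped_isrs
    }
    # a duplicate pair is symmetric: detecting the original instead of the
    # clone still removes exactly one of the pair
    originals_of_dups = {str(r.is_duplicate_of) for r in t.itertuples() if r.is_duplicate_of}
    dup_tp = len(detected & (injected_dups | originals_of_dups))

    case_versions: dict[str, int] = {}
    for r in t.itertuples():
        case_versions[str(r.case_id)] = case_versions.get(str(r.case_id), 0) + 1
    multiversion = {c for c, n in case_versions.items() if n > 1}
    surviving_per_case: dict[str, int] = {}
    for c in survivors:
        surviving_per_case[c.case_id] = surviving_per_case.get(c.case_id, 0) + 1
    resolved = sum(1 for c in multiversion if surviving_per_case.get(c, 0) <= 1)

    cat_by_name = {c.name: c for c in categories}
    consolidation_total = consolidation_correct = consolidation_wrong = 0
    category_total = category_correct = category_fp = 0
    for case in survivors:
        row = truth_by_isr[case.isr_id]
        study_mentions = [m for m in case.drugs if m.verbatim_name == row.injected_variant]
        if not study_mentions:
            # the pipeline never rewrites verbatim names, so a missing
            # recorded variant means the truth table is from another run
            raise ValueError(
                f"case {case.isr_id} does not carry this run's recorded drug name "
                f"{row.injected_variant!r}; ground truth from a different simulation?"
            )
        if row.category and row.category not in cat_by_name:
            raise ValueError(f"truth category {row.category!r} not in the supplied category set")
        if study_mentions:
            consolidation_total += 1
            assigned = {m.canonical_drug for m in study_mentions if m.canonical_drug}
            if row.drug in assigned:
                consolidation_correct += 1
            elif assigned:
                consolidation_wrong += 1
        if row.category:
            category_total += 1
            if case_matches(case, cat_by_name[row.category]):
                category_correct += 1
        else:
            if any(case_matches(case, c) for c in categories):
                category_fp += 1

    return RecoveryReport(
        n_truth_reports=len(t),
        n_survivors=len(survivors),
        dup_injected=len(injected_dups),
        dup_detected=len(detected),
        dup_true_positive=dup_tp,
        multiversion_cases=len(multiversion),
        multiversion_resolved=resolved,
        consolidation_total=consolidation_total,
        consolidation_correct=consolidation_correct,
        consolidation_wrong=consolidation_wrong,
        category_total=category_total,
        category_correct=category_correct,
        category_false_positive=category_fp,
    )
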