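# Methods

## The comparison model

`aerspipe` implements a reporting-rate comparison across drugs of one class
in a spontaneous-reporting database. For drug *d* and adverse-event category
*c*:

- **count** `n_dc`: number of deduplicated case reports that (i) match the
  category (at least one reaction term in the category's term set) and
  (ii) carry the drug in the requested suspect scope. *Primary suspect*
  counts require the primary-suspect role; *all suspect* accepts primary or
  secondary suspect. Concomitant and interacting mentions are excluded by
  default (a config switch includes them); a case contributes at most one
  count per (drug, category) regardless of reaction or mention multiplicity.
- **prescribing ratio** `PR_d = NRx_d / max_d' NRx_d'`, where `NRx_d` is the
  drug's summed new-prescription total over the study window. Rounded
  half-up to 4 decimals; the most-prescribed drug has PR = 1.
- **normalized rate** `r_dc = n_dc / PR_d` (reports per unit prescribing
  ratio), kept at full precision internally, displayed rounded half-up to
  an integer.
- **ranked risk** `RR_dc = round(100 · r_dc / max_d' r_d'c)`, half-up; the
  highest-rate drug in each category scores exactly 100.

The combined-category risk sums `n_dc` over a category list (a case matching
*k* categories contributes *k*; a unique-case mode counts it once), divides
by `PR_d`, and reports percent-of-maximum to one decimal.

Assumptions worth making explicit: NRx is a proxy for exposure, reporting
propensity is treated as comparable across drugs within the class, and the
statistic is purely relative — no confidence intervals or disproportionality
statistics (PRR/ROR/EBGM) are computed, and none are claimed.

### Rounding and the published table

All rounding is half-up (`decimal.Decimal`), never banker's. Feeding the
published myalgia counts and NRx totals through the pipeline reproduces the
published derived columns except two cells, both at rounding boundaries:
the rosuvastatin all-suspect rate computes to 6,960 against a printed 6,959
(2,019/0.2901 = 6,959.67, inconsistent with any single rounding rule), and
the lovastatin primary ranked risk computes to 6 against a printed 5
(100·311.19/5,656.67 = 5.5012, an exact half-up boundary). The acceptance
tests assert these two cells within one unit and every other cell exactly.

## Pipeline stages and their parameters

- **Parsing** (`aerspipe.io`): `$`-delimited per-table files with a header
  row (configurable delimiter/encoding/columns via `FileDialect`). Malformed
  lines are skipped into a rejects log with line numbers; undecodable bytes
  become U+FFFD and are counted. Reports need at least one drug and one
  reaction; others are excluded and counted. Receipt dates outside the
  study window (default 2005-07-01..2011-03-31) are dropped; undated reports
  are kept and flagged, since silently dropping them would bias counts.
- **Name consolidation** (`aerspipe.normalize`): normalization case-folds,
  strips bracketed qualifiers, converts punctuation to whitespace, and
  removes trailing dosage/strength/form tokens. Matching is exact against
  the dictionary first; fuzzy matching (Levenshtein via edlib) is a safety
  net with default `max_distance=1`, chosen so a single typo is recovered
  but curation is never overridden — an exact hit always wins, and a
  distance tie between two canonical drugs yields *no* match rather than a
  guess. Combination products match only if their full string is curated;
  no substring inference, which would create false consolidations.
- **Deduplication** (`aerspipe.dedup`): stage one keeps the latest report
  version per case key (date tie → largest ISR, so shuffling input cannot
  change the survivor). Stage two treats reports as duplicates only when
  they agree on the complete canonical drug set, complete reaction-term
  set, sex, and age (both present), with receipt dates within a window
  (default 30 days); the earliest report of a group survives. Both stages
  are idempotent, order-invariant, and conservative: every input report is
  either a survivor or appears in exactly one logged decision.
- **Categories** (`aerspipe.categories`): exact-term matching by default,
  because reactions in AERS-style extracts are coded preferred terms; a
  substring mode exists for deliberately broad categories. The shipped
  category file covers the four core muscle categories (myalgia,
  rhabdomyolysis, myositis, myopathy) as single-term lists plus three broad
  starting-point lists (joints/tendons, muscle atrophy/injury,
  coordination/weakness) that users should replace with study-specific
  terms.
- **Sensitivity variant**: `sensitivity_peak_rx` re-derives PRs from each
  drug's *peak annual* prescription count instead of the window sum,
  leaving everything else identical.

## The synthetic-data generator

`aerspipe.simulate.generate` emulates a multi-quarter extract with known
truth. Reports are drawn so the expected (drug, category) count is
proportional to prescribing weight × per-category reporting rate (rates in
reports per 10^6 prescriptions); the remainder of each drug's reports get
background reactions only. Signal reports carry one category term plus
Poisson(λ=1) background terms, which exercises the once-per-case counting
rule. Injected pathologies: name corruption (1..k random edits sparing the
first three characters, so distance-1 fuzzy matching stays meaningful, plus
dosage-suffix decoration), follow-up versions (same case key, 35–200 days
later), and duplicate submissions (field-identical clones under a new case
key, 0–5 days later). Demographics, reporter occupations, and non-exclusive
outcome codes are drawn from configurable mixes. The same seed yields
byte-identical files.

What the generator does **not** emulate: real MedDRA vocabularies and their
coding noise, reporting-propensity differences between drugs (stimulated
reporting, market-entry effects), dose data, and confounding structure.
Passing recovery tests therefore show the *pipeline machinery* is unbiased
under the stated generating process, not that real AERS inference is
unconfounded.

### Validation experiments and their scales

Test corpora use n = 600–10,000 reports; the recovery experiments use
n = 10,000 reports × 5 seeds with duplicate rate 0.05, follow-up rate 0.05,
and name corruption (p = 0.2, 1 edit). Reporting rates in those experiments
are set far above real-world levels (0.4–0.8 per prescription) so every
drug accumulates ≥ 2,000 matching cases, keeping seed noise on a recovered
ranked risk below one point.

Two interactions discovered during validation are properties of the method,
not bugs, and shape how the experiments are configured:

- **Duplicate-window collisions.** The agreement heuristic merges *any*
  field-identical pair within the window. In a dense stratum (thousands of
  reports sharing one category term), coincidentally identical
  non-duplicates occur at a rate growing with stratum density, biasing the
  densest drug's count down. The recovery experiments therefore set the
  window to 7 days — matched to the generator's 0–5-day duplicate-lag
  model — and the zero-noise equality check (a corpus with no duplicates at
  all) disables the heuristic stage, which exists only to remove
  duplicates. Real analyses should choose the window against their own
  duplicate-arrival model; the 30-day default is deliberately conservative
  for sparse data.
- **Follow-up/duplicate interaction.** When a report both receives a
  follow-up version and is cloned as a duplicate, version dedup keeps the
  later follow-up, pushing the surviving pair's date gap beyond the window;
  duplicate recall is therefore structurally below 1 on corpora with both
  noise types, and is asserted to be exactly 1 only with follow-ups off.

## Numerical and degenerate-input choices

- PR derivation uses exact `Decimal` arithmetic on integer NRx before
  rounding; equal maximal NRx values give several drugs PR = 1.
- All-zero rate vectors rank every drug 0 (with a warning) rather than
  dividing by zero; empty prescription tables, non-positive NRx, empty
  categories, and conflicting dictionary variants are fatal errors.
- Undated reports: kept through windowing (flagged), never merged by the
  duplicate heuristic, bucketed as `UNKNOWN` in yearly trends.
- Determinism: no stage consults global random state; the generator takes
  an explicit seed; pipeline reruns on identical inputs produce
  byte-identical outputs, verified by SHA-256 digests in the run manifest.

## Known limitations

- The full published variant lists (e.g. the 810 atorvastatin
  designations) and broad-category term lists are not reproduced; the
  shipped dictionary and categories are small curated fixtures.
- The published study's whole-database figures (total case counts,
  combined-category percentages across all muscle categories) require the
  full AERS extract and are out of reach of the shipped inputs; the package
  validates the arithmetic and the pipeline properties instead.
- Heuristic dedup is rule-based field agreement, not probabilistic record
  linkage, and over-merges dense strata (above); its decisions log exists
  precisely so such behaviour is auditable.
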