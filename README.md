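# aerspipe

Pharmacovigilance analysis of spontaneous adverse-event reports in the style
of the FDA's legacy Adverse Event Reporting System (AERS) quarterly extracts,
built for within-class drug safety comparisons — the motivating application
is muscle and tendon adverse events across the six statins (atorvastatin,
simvastatin, lovastatin, pravastatin, rosuvastatin, fluvastatin).

Spontaneous-report counts are unusable raw: drug names arrive as free text
(brands, generics, foreign names, misspellings, dosage strings), the same
case appears as follow-up versions and duplicate submissions, and report
volume scales with how often a drug is prescribed. `aerspipe` addresses each
problem as a separate, auditable stage:

1. **Parse** `$`-delimited per-table quarterly files (demographics, drug
   mentions with suspect-role codes, MedDRA-style reaction terms, outcome
   codes, report sources) and join them into case reports.
2. **Consolidate names** via a curated synonym dictionary, with optional
   bounded Levenshtein fuzzy matching as a misspelling safety net.
3. **Deduplicate**: keep the latest version per case key, then apply a
   conservative field-agreement heuristic for independently submitted
   duplicates. Every drop is logged as a decision record.
4. **Categorize** cases against named reaction-term search lists
   (e.g. Myalgia = {myalgia}).
5. **Rank**: for drug *d* with report count *n_d* and summed
   new-prescription total NRx_d, the prescribing ratio is
   PR_d = NRx_d / max_d' NRx_d', the normalized rate is n_d / PR_d, and the
   **ranked risk** is 100 × (n_d / PR_d) / max_d' (n_d' / PR_d'), so the
   highest-rate drug in each category scores 100.

A synthetic report generator with per-report ground truth (known true drug,
category, duplicate/follow-up links, injected name corruptions) makes every
stage testable without access to FDA data.

## Worked example

The package ships the published inputs of the statin myalgia analysis: the
six summed NRx totals (2005-07 through 2011-03) and the per-statin myalgia
report counts for both suspect scopes. Ranking them:

```sh
aerspipe rank --counts myalgia_counts.csv --prescriptions statin_nrx.csv
```

prints

```
        drug  primary_count  all_count     pr  primary_rate  all_rate  ranked_primary  ranked_all
rosuvastatin           1641       2019 0.2901          5657      6960             100         100
 fluvastatin            103        184 0.0265          3887      6943              69         100
atorvastatin           2751       3667 0.8604          3197      4262              57          61
 pravastatin            257        541 0.2275          1130      2378              20          34
 simvastatin           1003       1827 1.0000          1003      1827              18          26
  lovastatin             67        189 0.2153           311       878               6          13
```

Reading the first row: rosuvastatin drew 1,641 primary-suspect myalgia
reports despite a prescribing ratio of only 0.2901, giving the highest
normalized rate (5,657 reports per unit prescribing ratio) and therefore
ranked risk 100 in both scopes. Simvastatin, the most-prescribed statin
(PR = 1), ranks only 18 — its large raw count is explained by market size.
Fluvastatin's rank of 69/100 despite tiny counts reflects its very small
denominator (PR = 0.0265).

The same tables are produced end to end from raw quarterly files with
`aerspipe run`; `aerspipe simulate` generates synthetic quarterly files from
a YAML scenario, and `aerspipe match-drugs` / `aerspipe dedup` expose the
intermediate stages.

Python API: the same example in code —

```python
from aerspipe import prescribing_ratios, risk_table_from_counts
from aerspipe.datasets import myalgia_counts, statin_nrx

pr = prescribing_ratios(statin_nrx())     # simvastatin = 1.0000
mc = myalgia_counts()
table = risk_table_from_counts(
    dict(zip(mc.drug, mc.primary_count)),
    dict(zip(mc.drug, mc.all_count)),
    pr,
)
```

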