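"""Accessors for the small reference tables shipped with the package.

These are the published inputs of the statin muscle-event analysis: the
summed new-prescription (NRx) totals for the six statins over the study
window, and the published myalgia report counts per drug and suspect scope.
They let the ranking arithmetic be exercised and reproduced without any
access to the underlying report database.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .metrics import PrescriptionTable
from .normalize import SynonymDictionary


def _data_path(name: str):
    return resources.as_file(resources.files("aerspipe.data") / name)


def statin_nrx() -> dict[str, int]:
    """Summed quarterly NRx totals (2005-07..2011-03) for the six statins."""
    with _data_path("statin_nrx.csv") as p:
        df = pd.read_csv(p)
    return dict(zip(df["drug"], df["nrx"].astype(int)))


def statin_prescribing_ratios() -> PrescriptionTable:
    """Prescribing ratios derived from :func:`statin_nrx` (simvastatin = 1)."""
    from .metrics import prescribing_ratios

    return prescribing_ratios(statin_nrx())


def myalgia_counts() -> pd.DataFrame:
    """Published per-statin myalgia report counts, both suspect scopes.

    Columns: drug, primary_count, all_count.
    """
    with _data_path("myalgia_counts.csv") as p:
        return pd.read_csv(p)


def statin_synonyms() -> SynonymDictionary:
    """The curated statin synonym dictionary shipped with the package."""
    with _data_path("statin_synonyms.csv") as p:
        return SynonymDictionary.from_csv(p)


def default_category_path() -> Path:
    """Filesystem path of the shipped category definitions (read-only)."""
    with _data_path("categories.yml") as p:
        return Path(p)
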