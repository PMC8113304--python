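"""Bundled reference tables.

Three small transcriptions of the published summary tables of a
season-long daily pollen monitoring study ship with the package (the raw
daily residue matrix itself was published only as supplementary material
and is emulated by :mod:`pollenhq.simulate`):

* the 29-analyte detected-pesticide panel with LOQ, recovery, LD50 and
  the reported per-analyte hazard summary columns,
* the per-day PHQ contribution table for the fifteen days whose total
  PHQ exceeded the relevance threshold,
* the class breakdown of the 262-substance screening panel.

The per-day table was recovered from a concatenated text rendering of
the printed table; each PHQ/concentration pair was validated against the
panel's LD50 ratios and each row against its printed totals.  A few
cell-to-analyte assignments are best-effort (the PHQ values and row sums
are unambiguous); treat the ``analyte`` labels of small contributions
with care.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_pesticide_table
from .model import PesticidePanel

__all__ = [
    "load_panel",
    "load_panel_table",
    "load_tphq_day_contributions",
    "load_tphq_day_totals",
    "load_screening_counts",
]


def _data_path(name: str):
    return resources.files("pollenhq.data").joinpath(name)


def load_panel() -> PesticidePanel:
    """The 29 detected analytes as a :class:`~pollenhq.model.PesticidePanel`."""
    with resources.as_file(_data_path("pesticide_panel.csv")) as p:
        return read_pesticide_table(p)


def load_panel_table() -> pd.DataFrame:
    """Full panel transcription including the reported summary columns
    (``df_days``, ``max_conc_ng_g``, ``mean_conc_ng_g``,
    ``phq_max_reported``, ``mean_phq_reported``)."""
    with resources.as_file(_data_path("pesticide_panel.csv")) as p:
        return pd.read_csv(p, na_values=["–", "-"]).set_index("name")


def load_tphq_day_contributions() -> pd.DataFrame:
    """Long table of per-day PHQ contributions (day, analyte, phq, conc)."""
    with resources.as_file(_data_path("tphq_day_contributions.csv")) as p:
        return pd.read_csv(p)


def load_tphq_day_totals() -> pd.DataFrame:
    """Printed per-day totals (detect count, tPHQ, total concentration)."""
    with resources.as_file(_data_path("tphq_day_totals.csv")) as p:
        return pd.read_csv(p).set_index("day")


def load_screening_counts() -> dict[str, int]:
    """Class breakdown of the full screening panel (262 substances)."""
    with resources.as_file(_data_path("screening_panel_counts.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["class"], df["count"].astype(int)))
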