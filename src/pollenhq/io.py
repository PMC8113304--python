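"""Delimited-text I/O for pesticide panels and daily residue matrices.

File conventions (documented, fixed):

* Panel file columns: ``name, class, group, areas, loq_ng_g, recovery_pct,
  ld50_ug_bee, b1, approved_de``.  Extra columns are ignored.  ``class``
  accepts ``F``/``H``/``I`` or full words; ``areas`` is a ``;``-separated
  set of opaque codes; ``ld50_ug_bee`` and ``recovery_pct`` accept ``-``,
  ``–`` or an empty cell as "not available".
* Residue matrix: wide, first columns ``day_index`` and ``date``
  (ISO-8601), one further column per analyte.  Empty cells or the literal
  ``ND`` mean not detected; ``0`` is treated as ND with a warning; the
  literal ``MASKED`` round-trips a masked detection.
* Delimiter: comma or tab, auto-detected from the header line.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from os import PathLike
from typing import Iterable

import pandas as pd

from .model import DailySample, PesticidePanel, PesticideProperty, ResidueSeries

__all__ = [
    "read_pesticide_table",
    "read_residue_matrix",
    "write_residue_matrix",
    "write_pesticide_table",
]

_NA_TOKENS = {"", "-", "–", "—", "na", "n/a", "nan", "none"}
_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}

PANEL_COLUMNS = [
    "name", "class", "group", "areas", "loq_ng_g", "recovery_pct",
    "ld50_ug_bee", "b1", "approved_de",
]


def _sniff_delimiter(path: str | PathLike) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _parse_optional_float(cell, locator: str, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text.lower() in _NA_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"{locator}: cannot parse {column}={cell!r}") from None


def _parse_bool(cell, default: bool) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return default
    text = str(cell).strip().lower()
    if text in _NA_TOKENS:
        return default
    return text in _TRUE_TOKENS


def read_pesticide_table(
    path: str | PathLike, delimiter: str | None = None
) -> PesticidePanel:
    """Read a pesticide panel from delimited text, preserving row order.

    Raises ``ValueError`` naming the offending row for duplicate names,
    non-positive LOQs, or unknown class codes.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"name", "class", "loq_ng_g"} - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing required columns: {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        loc = f"row {i + 2} ({row['name']!r})"  # +2: header + 1-based
        loq = _parse_optional_float(row["loq_ng_g"], loc, "loq_ng_g")
        if loq is None or loq <= 0:
            raise ValueError(f"{loc}: LOQ must be a positive number")
        try:
            entry = PesticideProperty(
                name=str(row["name"]).strip(),
                pclass=row["class"],
                group=str(row.get("group", "")).strip(),
                application_areas=frozenset(
                    a.strip() for a in str(row.get("areas", "")).split(";")
                    if a.strip()
                ),
                loq=loq,
                recovery_pct=_parse_optional_float(
                    row.get("recovery_pct"), loc, "recovery_pct"),
                ld50_oral=_parse_optional_float(
                    row.get("ld50_ug_bee"), loc, "ld50_ug_bee"),
                bee_hazard_b1=_parse_bool(row.get("b1"), False),
                approved_de=_parse_bool(row.get("approved_de"), True),
            )
        except ValueError as exc:
            raise ValueError(f"{loc}: {exc}") from None
        entries.append(entry)
    try:
        return PesticidePanel(entries)
    except ValueError as exc:
        raise ValueError(f"panel file {path}: {exc}") from None


def write_pesticide_table(
    panel: PesticidePanel, path: str | PathLike, delimiter: str = ","
) -> None:
    rows = []
    for e in panel:
        rows.append({
            "name": e.name,
            "class": e.pclass,
            "group": e.group,
            "areas": ";".join(sorted(e.application_areas)),
            "loq_ng_g": _fmt(e.loq),
            "recovery_pct": _fmt(e.recovery_pct) if e.recovery_pct is not None else "",
            "ld50_ug_bee": _fmt(e.ld50_oral) if e.ld50_oral is not None else "",
            "b1": int(e.bee_hazard_b1),
            "approved_de": int(e.approved_de),
        })
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(
        path, sep=delimiter, index=False)


#: Significant digits preserved by the residue writer; the read∘write
#: round-trip is exact up to this formatting precision.
WRITE_SIGFIGS = 9


def _fmt(value: float) -> str:
    return f"{value:.{WRITE_SIGFIGS}g}"


def read_residue_matrix(
    path: str | PathLike,
    panel: PesticidePanel,
    delimiter: str | None = None,
) -> ResidueSeries:
    """Read a wide daily residue matrix against a panel.

    The returned series is *uncensored*: values below LOQ are kept as read
    (censoring is a quality-control step).  Unknown analyte columns,
    non-monotone dates and negative concentrations are rejected.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("day_index", "date"):
        if col not in df.columns:
            raise ValueError(f"residue matrix missing column {col!r}")
    analyte_cols = [c for c in df.columns if c not in ("day_index", "date")]
    unknown = [c for c in analyte_cols if c not in panel]
    if unknown:
        raise ValueError(f"residue matrix columns not in panel: {unknown}")

    samples = []
    for i, row in df.iterrows():
        loc = f"row {i + 2}"
        day_index = int(row["day_index"])
        date = _dt.date.fromisoformat(str(row["date"]).strip())
        conc: dict[str, float] = {}
        for a in analyte_cols:
            cell = str(row[a]).strip()
            if cell == "" or cell.upper() == "ND":
                continue
            if cell.upper() == "MASKED":
                conc[a] = float("nan")
                continue
            value = float(cell)
            if value < 0:
                raise ValueError(f"{loc}: {a}: negative concentration {value}")
            if value == 0:
                warnings.warn(
                    f"{loc}: {a}: 0 treated as not detected", stacklevel=2)
                continue
            conc[a] = value
        samples.append(DailySample(day_index, date, conc))
    try:
        return ResidueSeries(samples, panel)
    except ValueError as exc:
        raise ValueError(f"residue matrix {path}: {exc}") from None


def write_residue_matrix(
    series: ResidueSeries,
    path: str | PathLike,
    delimiter: str = ",",
    analytes: Iterable[str] | None = None,
) -> None:
    """Write a series as a wide matrix (ND as empty cell, masked as MASKED)."""
    cols = list(analytes) if analytes is not None else series.panel.names
    rows = []
    for s in series:
        row: dict[str, object] = {
            "day_index": s.day_index, "date": s.date.isoformat()}
        for a in cols:
            c = s.concentrations.get(a)
            if c is None:
                row[a] = ""
            elif math.isnan(c):
                row[a] = "MASKED"
            else:
                row[a] = _fmt(c)
        rows.append(row)
    pd.DataFrame(rows, columns=["day_index", "date", *cols]).to_csv(
        path, sep=delimiter, index=False)
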