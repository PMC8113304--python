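"""Pooling/dilution analysis: what multi-day composites hide.

Monitoring programmes often pool pollen over many days before analysis.
Assuming equal daily pollen mass, the concentration measured in a pooled
sample is the arithmetic mean of the daily concentrations over the pooled
days, with not-detected days contributing zero residue mass.  A single
spray-event pulse therefore appears *diluted*: its one-day maximum ``c``
inside a ``k``-day pool shows up as roughly ``c/k``.

The *dilution factor* of an analyte is its season maximum daily
concentration divided by the pooled mean of the window containing that
maximum — the factor by which a pooled design underestimates the worst
single-day exposure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .model import ResidueSeries

__all__ = ["WindowSpec", "PoolSummary", "pool_series", "dilution_report"]


@dataclass(frozen=True)
class WindowSpec:
    """A pooling window: ``k``-day blocks anchored at D1, or calendar months.

    ``kind`` is ``"k_day"`` (with ``k >= 1``) or ``"calendar_month"``.
    k-day blocks tile the sampled days from the first day index
    (D1..Dk, Dk+1..D2k, ...); month windows group samples by the calendar
    month of their date.
    """

    kind: str = "k_day"
    k: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("k_day", "calendar_month"):
            raise ValueError(f"unknown window kind: {self.kind!r}")
        if self.kind == "k_day" and self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.k}-day" if self.kind == "k_day" else "calendar-month"

    @classmethod
    def parse(cls, text: str | int) -> "WindowSpec":
        """Parse ``"k_day:10"``, ``10`` or ``"calendar_month"``."""
        if isinstance(text, int):
            return cls("k_day", text)
        t = str(text).strip()
        if t == "calendar_month":
            return cls("calendar_month")
        if t.startswith("k_day:"):
            return cls("k_day", int(t.split(":", 1)[1]))
        return cls("k_day", int(t))


@dataclass
class PoolSummary:
    """Pooled means and dilution factors for one window specification.

    pooled_means:
        window × analyte DataFrame of pooled concentrations (ND = 0).
    dilution_factor:
        per-analyte ``max daily conc / pooled mean of the window holding
        that max``; NaN for analytes never quantified.
    """

    window: WindowSpec
    pooled_means: pd.DataFrame
    dilution_factor: pd.Series
    max_daily: pd.Series


def _window_labels(series: ResidueSeries, window: WindowSpec) -> list:
    if window.kind == "calendar_month":
        return [s.date.strftime("%Y-%m") for s in series]
    first = series.samples[0].day_index if len(series) else 1
    k = window.k
    if len(series) and k > len(series):
        warnings.warn(
            f"window k={k} exceeds series length {len(series)}; "
            "using a single window", stacklevel=3)
    labels = []
    for s in series:
        block = (s.day_index - first) // k
        lo, hi = first + block * k, first + (block + 1) * k - 1
        labels.append(f"D{lo}-D{hi}")
    return labels


def pool_series(series: ResidueSeries, window: WindowSpec | str | int,
                nd: str = "zero") -> PoolSummary:
    """Pool a censored series over a window specification.

    Pooled mean = arithmetic mean over *sampled* days in the window, with
    not-detected (and masked) days contributing 0 — the equal-daily-mass
    physical mixing model.  ``nd="half_loq"`` substitutes LOQ/2 for
    censored days instead (sensitivity analysis).  Requires at least one
    sample.
    """
    if not isinstance(window, WindowSpec):
        window = WindowSpec.parse(window)
    if not len(series):
        raise ValueError("cannot pool an empty series")
    if nd not in ("zero", "half_loq"):
        raise ValueError(f"unknown ND strategy: {nd!r}")
    frame = series.to_frame()
    if nd == "half_loq":
        fill = {a: series.panel[a].loq / 2.0 for a in frame.columns}
        frame = frame.fillna(pd.Series(fill))
    else:
        frame = frame.fillna(0.0)
    labels = _window_labels(series, window)
    grouper = pd.Series(labels, index=frame.index, name="window")
    pooled = frame.groupby(grouper, sort=False).mean()

    raw = series.to_frame()
    max_daily = raw.max(axis=0, skipna=True)
    factors = {}
    for a in frame.columns:
        col = raw[a]
        if col.notna().sum() == 0 or not max_daily[a] > 0:
            factors[a] = float("nan")
            continue
        peak_day = col.idxmax(skipna=True)
        pool_of_peak = pooled.loc[grouper.loc[peak_day], a]
        factors[a] = float(max_daily[a] / pool_of_peak)
    return PoolSummary(
        window=window,
        pooled_means=pooled,
        dilution_factor=pd.Series(factors, name="dilution_factor"),
        max_daily=max_daily.rename("max_daily_conc"),
    )


def dilution_report(series: ResidueSeries,
                    analytes: list[str] | None = None,
                    windows: list[WindowSpec | str | int] = (10, "calendar_month"),
                    ) -> pd.DataFrame:
    """One row per (analyte, window): daily max vs pooled mean vs factor.

    Analytes never quantified get max 0 and an undefined (NaN) factor.
    """
    analytes = analytes if analytes is not None else series.panel.names
    rows = []
    for w in windows:
        summary = pool_series(series, w)
        for a in analytes:
            mx = summary.max_daily.get(a, float("nan"))
            mx = 0.0 if (isinstance(mx, float) and math.isnan(mx)) else float(mx)
            factor = summary.dilution_factor.get(a, float("nan"))
            pooled_at_max = (mx / factor
                             if factor and not math.isnan(factor) else float("nan"))
            rows.append({
                "analyte": a,
                "window": summary.window.label,
                "max_daily_conc": mx,
                "pooled_mean_at_max": pooled_at_max,
                "dilution_factor": factor,
            })
    return pd.DataFrame(rows, columns=[
        "analyte", "window", "max_daily_conc", "pooled_mean_at_max",
        "dilution_factor"])
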