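"""Pollen hazard quotient (PHQ) scoring.

The PHQ is a unitless exposure-toxicity screening score for bee pollen:
the residue concentration in ng/g pollen (ppb) divided by the acute oral
honey-bee LD50 in μg/bee.  By convention no unit conversion is applied —
the quotient is a screening index, not a physical dose fraction.

Derived quantities:

``PHQmax``
    PHQ at an analyte's maximum detected concentration over the season.
``mean PHQ``
    PHQ at the analyte's mean concentration over its detection days.
``tPHQday``
    Sum of all *defined* per-analyte PHQs within one daily sample; days
    whose tPHQday exceeds a relevance threshold (default 50, strict) are
    deemed relevant for bee health.
``LD50 fraction``
    The percent of the LD50 a nurse bee would ingest per day (and per
    nursing period) when consuming pollen at the scored contamination,
    assuming a fixed daily bee-bread consumption.

Analytes without an LD50 have *undefined* PHQs: they are excluded from
tPHQday and listed separately, never silently scored as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .model import CLASSES, ResidueSeries

__all__ = [
    "HazardConfig",
    "HazardTable",
    "phq",
    "round_sigfigs",
    "hazard_summary",
    "classify_relevance",
    "relevant_days",
    "ld50_fraction",
    "class_decomposition",
]


@dataclass(frozen=True)
class HazardConfig:
    """Scoring parameters.

    relevance_threshold:
        tPHQday level above which a day is "relevant" (default 50).  The
        comparison is strict (``>``) by default; set
        ``inclusive_threshold=True`` for a ``>=`` reading.
    consumption_mg_day:
        Bee-bread consumption of one nurse bee, mg/day (default 9.5).
    nursing_period_days:
        Length of the nursing period for cumulative intake (default 10).
    report_sigfigs:
        Significant figures for reported (not internal) values, default 2.
    """

    relevance_threshold: float = 50.0
    consumption_mg_day: float = 9.5
    nursing_period_days: int = 10
    report_sigfigs: int = 2
    inclusive_threshold: bool = False

    def __post_init__(self) -> None:
        for name in ("relevance_threshold", "consumption_mg_day",
                     "nursing_period_days", "report_sigfigs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def round_sigfigs(x: float, sigfigs: int) -> float:
    """Round ``x`` to ``sigfigs`` significant figures.

    Ties round half away from zero in decimal (the convention of printed
    report tables), so 0.95 at one significant figure is 1.0, not 0.9.
    """
    x = float(x)
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    exponent = d.adjusted() - sigfigs + 1
    return float(d.quantize(Decimal(1).scaleb(exponent),
                            rounding=ROUND_HALF_UP))


def phq(conc: float, ld50: float | None) -> float | None:
    """PHQ of one detection: ``conc [ng/g] / ld50 [μg/bee]``.

    Returns ``None`` (undefined) when the LD50 is absent or the
    concentration is masked; raises for a non-positive LD50.
    """
    if ld50 is None:
        return None
    if ld50 <= 0:
        raise ValueError(f"LD50 must be > 0, got {ld50}")
    if conc is None or math.isnan(conc):
        return None
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return conc / ld50


@dataclass
class HazardTable:
    """Season-level hazard summary.

    per_analyte:
        DataFrame indexed by analyte: ``phq_max, mean_phq, max_conc,
        mean_detected_conc, detection_frequency, pclass``.
    contributions:
        day × analyte DataFrame of per-detection PHQs (NaN when absent or
        undefined); ``tphq`` is its row sum.
    tphq:
        Series of tPHQday per sampled day (0 for days with no defined PHQ).
    class_shares / class_conc:
        day × class decomposition of tPHQday and of total concentration.
    undefined_analytes:
        analytes detected but without LD50 (excluded from tPHQday).
    """

    per_analyte: pd.DataFrame
    contributions: pd.DataFrame
    tphq: pd.Series
    class_shares: pd.DataFrame
    class_conc: pd.DataFrame
    undefined_analytes: set[str] = field(default_factory=set)
    config: HazardConfig = field(default_factory=HazardConfig)

    def reported_per_analyte(self) -> pd.DataFrame:
        """Per-analyte table rounded to the configured significant figures."""
        n = self.config.report_sigfigs
        out = self.per_analyte.copy()
        for col in ("phq_max", "mean_phq", "max_conc", "mean_detected_conc"):
            out[col] = out[col].map(
                lambda v: round_sigfigs(v, n) if pd.notna(v) else v)
        return out


def hazard_summary(series: ResidueSeries,
                   cfg: HazardConfig = HazardConfig()) -> HazardTable:
    """Score a censored (and QC-masked) residue series.

    Per analyte, ``phq_max`` applies :func:`phq` to the maximum quantified
    concentration and ``mean_phq`` to the mean over detection days; per
    day, tPHQday sums the defined contributions only.
    """
    frame = series.to_frame()  # day x analyte, NaN = ND or masked
    mask = series.detection_mask()

    rows = []
    undefined: set[str] = set()
    for e in series.panel:
        col = frame[e.name]
        det_days = int(mask[e.name].sum())
        quantified = col.dropna()
        max_c = float(quantified.max()) if len(quantified) else float("nan")
        mean_c = float(quantified.mean()) if len(quantified) else float("nan")
        if e.ld50_oral is None:
            if det_days:
                undefined.add(e.name)
            pmax = pmean = float("nan")
        else:
            pmax = max_c / e.ld50_oral if len(quantified) else float("nan")
            pmean = mean_c / e.ld50_oral if len(quantified) else float("nan")
        rows.append({
            "analyte": e.name, "pclass": e.pclass,
            "detection_frequency": det_days,
            "max_conc": max_c, "mean_detected_conc": mean_c,
            "phq_max": pmax, "mean_phq": pmean,
        })
    per_analyte = pd.DataFrame(rows).set_index("analyte")

    ld50 = pd.Series(
        {e.name: (e.ld50_oral if e.ld50_oral is not None else np.nan)
         for e in series.panel})
    contributions = frame.div(ld50, axis=1)
    tphq = contributions.sum(axis=1, skipna=True)

    pclass = pd.Series({e.name: e.pclass for e in series.panel})
    class_shares = contributions.T.groupby(pclass).sum(min_count=0).T
    class_conc = frame.T.groupby(pclass).sum(min_count=0).T
    for c in CLASSES:  # always report all three classes
        for table in (class_shares, class_conc):
            if c not in table.columns:
                table[c] = 0.0
    class_shares = class_shares[list(CLASSES)]
    class_conc = class_conc[list(CLASSES)]

    return HazardTable(
        per_analyte=per_analyte,
        contributions=contributions,
        tphq=tphq,
        class_shares=class_shares,
        class_conc=class_conc,
        undefined_analytes=undefined,
        config=cfg,
    )


def classify_relevance(tphq: float, cfg: HazardConfig = HazardConfig()) -> bool:
    """Is a daily total PHQ "relevant" for bee health?

    Strict ``tphq > threshold`` by default; a day exactly at the
    threshold is not relevant unless ``cfg.inclusive_threshold``.
    """
    if tphq < 0:
        raise ValueError("tPHQ must be >= 0")
    if cfg.inclusive_threshold:
        return tphq >= cfg.relevance_threshold
    return tphq > cfg.relevance_threshold


def relevant_days(table: HazardTable,
                  cfg: HazardConfig | None = None) -> list[int]:
    """Day indices whose tPHQday exceeds the relevance threshold."""
    cfg = cfg or table.config
    return [int(d) for d, v in table.tphq.items() if classify_relevance(v, cfg)]


def ld50_fraction(phq_value: float,
                  cfg: HazardConfig = HazardConfig()) -> tuple[float, float]:
    """Percent of the LD50 ingested at a given PHQ.

    With concentration ``= phq × LD50`` (ng/g over μg/bee) and a daily
    consumption of ``m`` mg bee bread, the ingested dose is
    ``phq × LD50 × m × 1e-6`` μg, i.e. a fraction ``phq × m × 1e-6`` of
    the LD50.  Returns ``(percent_per_day, percent_per_nursing_period)``;
    a PHQ of 100 at 9.5 mg/day gives 0.095 ≈ 0.1 %/day and 0.95 ≈ 1% over
    a 10-day nursing period.
    """
    if phq_value < 0:
        raise ValueError("PHQ must be >= 0")
    daily_pct = phq_value * cfg.consumption_mg_day * 1e-6 * 100.0
    return daily_pct, daily_pct * cfg.nursing_period_days


def class_decomposition(table: HazardTable) -> pd.DataFrame:
    """Per-day stacked shares by pesticide class.

    Returns a day-indexed DataFrame with, per class, the absolute tPHQ and
    concentration contributions and their fractional shares (NaN share on
    empty days).  Shares sum to 1 on any day with detections.
    """
    out = pd.DataFrame(index=table.tphq.index)
    tot_phq = table.class_shares.sum(axis=1)
    tot_conc = table.class_conc.sum(axis=1)
    for c in CLASSES:
        out[f"tphq_{c}"] = table.class_shares[c]
        out[f"conc_{c}"] = table.class_conc[c]
        out[f"tphq_share_{c}"] = table.class_shares[c] / tot_phq.where(tot_phq > 0)
        out[f"conc_share_{c}"] = table.class_conc[c] / tot_conc.where(tot_conc > 0)
    out["tphq_total"] = tot_phq
    out["conc_total"] = tot_conc
    return out
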