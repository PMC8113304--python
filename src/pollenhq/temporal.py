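"""Detection-frequency, persistence-run and co-application analysis.

A *detection run* is a maximal stretch of detection days for one analyte
in which interruptions of at most ``gap_tolerance`` consecutive sampled
not-detected days are bridged.  Days without a sample (rain days) are
observationally neutral: they neither extend nor break a run, and they do
not count toward the gap budget.  Each run records its peak (earliest day
wins on ties), the days from onset to peak, and the days from peak to
clearance — the field pattern being a spray-event pulse of roughly ten
days peaking within the first five.

A *co-application score* quantifies whether two analytes move together as
one formulation would: the linear correlation of log-concentrations over
shared detection days and the coefficient of variation of their
concentration ratio (a truly co-applied pair at fixed formulation ratio
has correlation near 1 and ratio CV near the measurement noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ResidueSeries

__all__ = [
    "DetectionRun",
    "CoApplicationScore",
    "detection_frequency",
    "residues_per_day",
    "detect_runs",
    "peak_timing_summary",
    "coapplication",
    "coapplication_table",
]

#: minimum shared detection days for a defined co-application score
MIN_SHARED_DAYS = 3


@dataclass(frozen=True)
class DetectionRun:
    """One gap-tolerant detection period of one analyte."""

    analyte: str
    start_day: int
    end_day: int
    length_days: int          # sampled days spanned: detections + tolerated gaps
    peak_day: int | None      # None when every detection in the run is masked
    peak_conc: float
    days_to_peak: int | None  # peak_day - start_day + 1
    days_to_clearance: int | None  # end_day - peak_day
    internal_gaps: int        # tolerated sampled ND days inside the run

    def __post_init__(self) -> None:
        if not (self.start_day <= self.end_day):
            raise ValueError("run start must not exceed end")
        if self.peak_day is not None and not (
                self.start_day <= self.peak_day <= self.end_day):
            raise ValueError("peak day must lie within the run")


@dataclass(frozen=True)
class CoApplicationScore:
    """Pairwise co-application evidence over shared detection days.

    ``concentration_correlation`` and ``ratio_cv`` are ``None`` when fewer
    than :data:`MIN_SHARED_DAYS` shared quantified days exist.
    """

    analyte_a: str
    analyte_b: str
    shared_detection_days: int
    concentration_correlation: float | None
    ratio_cv: float | None

    @property
    def defined(self) -> bool:
        return self.concentration_correlation is not None


def detection_frequency(series: ResidueSeries) -> pd.Series:
    """Per-analyte count of detection days (d_f); 0 for never-detected."""
    return series.detection_mask().sum(axis=0).rename("d_f")


def residues_per_day(series: ResidueSeries) -> tuple[pd.Series, dict]:
    """Detection counts per sampled day plus median/min/max over days.

    Days with zero detections count; the summary also reports how many
    sampled days carried no residue at all.
    """
    counts = series.detection_mask().sum(axis=1).rename("n_residues")
    if len(counts):
        summary = {
            "median": float(counts.median()),
            "min": int(counts.min()),
            "max": int(counts.max()),
            "days_without_residues": int((counts == 0).sum()),
        }
    else:
        summary = {"median": 0.0, "min": 0, "max": 0,
                   "days_without_residues": 0}
    return counts, summary


def detect_runs(series: ResidueSeries, analyte: str,
                gap_tolerance: int = 1) -> list[DetectionRun]:
    """Extract ordered, disjoint detection runs for one analyte.

    Gaps are counted in *sampled* days: a stretch of more than
    ``gap_tolerance`` consecutive not-detected samples ends the run, while
    unsampled calendar days in between are ignored entirely.
    """
    if analyte not in series.panel:
        raise KeyError(f"analyte {analyte!r} not in panel")
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")

    # (day_index, conc-or-NaN) for days where the analyte was detected,
    # with the count of sampled ND days separating consecutive detections.
    events: list[tuple[int, float, int]] = []  # (day, conc, nd_days_before)
    nd_since_last = 0
    seen_first = False
    for s in series:
        if analyte in s.concentrations:
            events.append((s.day_index, s.concentrations[analyte],
                           nd_since_last if seen_first else 0))
            nd_since_last = 0
            seen_first = True
        else:
            nd_since_last += 1

    runs: list[DetectionRun] = []
    current: list[tuple[int, float]] = []
    gaps = 0

    def flush() -> None:
        nonlocal current, gaps
        if not current:
            return
        days = [d for d, _ in current]
        quantified = [(d, c) for d, c in current if not math.isnan(c)]
        if quantified:
            peak_conc = max(c for _, c in quantified)
            peak_day = min(d for d, c in quantified if c == peak_conc)
            days_to_peak = peak_day - days[0] + 1
            clearance = days[-1] - peak_day
        else:
            peak_conc, peak_day, days_to_peak, clearance = (
                float("nan"), None, None, None)
        runs.append(DetectionRun(
            analyte=analyte, start_day=days[0], end_day=days[-1],
            length_days=len(days) + gaps, peak_day=peak_day, peak_conc=peak_conc,
            days_to_peak=days_to_peak, days_to_clearance=clearance,
            internal_gaps=gaps))
        current, gaps = [], 0

    for day, conc, nd_before in events:
        if current and nd_before > gap_tolerance:
            flush()
            nd_before = 0
        if current:
            gaps += nd_before
        current.append((day, conc))
    flush()
    return runs


def peak_timing_summary(runs: list[DetectionRun],
                        early_peak_days: int = 5) -> dict:
    """Distribution of onset-to-peak and peak-to-clearance times.

    Returns quartiles of both timings and the fraction of runs peaking
    within ``early_peak_days`` of onset; empty input gives an empty dict.
    Runs without a quantified peak are ignored.
    """
    to_peak = [r.days_to_peak for r in runs if r.days_to_peak is not None]
    to_clear = [r.days_to_clearance for r in runs
                if r.days_to_clearance is not None]
    if not to_peak:
        return {}
    q = [0, 25, 50, 75, 100]
    return {
        "n_runs": len(to_peak),
        "days_to_peak_quartiles": [float(v) for v in
                                   np.percentile(to_peak, q)],
        "days_to_clearance_quartiles": [float(v) for v in
                                        np.percentile(to_clear, q)],
        "fraction_peak_within": float(
            np.mean([d <= early_peak_days for d in to_peak])),
        "early_peak_days": early_peak_days,
    }


def coapplication(series: ResidueSeries, a: str, b: str,
                  min_shared: int = MIN_SHARED_DAYS,
                  log_scale: bool = True) -> CoApplicationScore:
    """Score a pair of analytes for joint application.

    Correlation is computed on log-concentrations by default (residue
    noise is multiplicative); ``ratio_cv`` is the sample CV of ``a/b``
    over days where both are quantified.
    """
    if a == b:
        raise ValueError("co-application requires two distinct analytes")
    frame = series.to_frame(analytes=[a, b]).dropna()
    n = len(frame)
    if n < min_shared:
        return CoApplicationScore(a, b, n, None, None)
    xa, xb = frame[a].to_numpy(float), frame[b].to_numpy(float)
    la, lb = (np.log(xa), np.log(xb)) if log_scale else (xa, xb)
    if np.std(la) == 0 or np.std(lb) == 0:
        corr = 1.0 if np.allclose(la - la.mean(), lb - lb.mean()) else float("nan")
    else:
        corr = float(np.corrcoef(la, lb)[0, 1])
    ratio = xa / xb
    mean_ratio = float(ratio.mean())
    cv = float(ratio.std(ddof=1) / mean_ratio) if mean_ratio else float("nan")
    return CoApplicationScore(a, b, n, corr, cv)


def coapplication_table(series: ResidueSeries,
                        pairs: list[tuple[str, str]],
                        **kwargs) -> pd.DataFrame:
    """Tabulate :func:`coapplication` for a list of analyte pairs."""
    rows = []
    for a, b in pairs:
        s = coapplication(series, a, b, **kwargs)
        rows.append({
            "analyte_a": a, "analyte_b": b,
            "shared_detection_days": s.shared_detection_days,
            "concentration_correlation": s.concentration_correlation,
            "ratio_cv": s.ratio_cv,
            "defined": s.defined,
        })
    return pd.DataFrame(
        rows, columns=["analyte_a", "analyte_b", "shared_detection_days",
                       "concentration_correlation", "ratio_cv", "defined"])
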