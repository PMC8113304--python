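"""Quality control: recovery-rate screening and LOQ censoring.

Two reliability decisions precede any hazard scoring of a residue matrix:

1. *Recovery screening.*  Analytes whose spike recovery falls outside an
   acceptance band are flagged; an analyte with a recovery so low that its
   quantification is meaningless (default < 10%) is *excluded* — its
   concentrations are masked downstream, though the detection days
   themselves remain reportable.
2. *LOQ censoring.*  Concentrations below an analyte's limit of
   quantification are left-censored to "not detected".  A value exactly at
   the LOQ counts as detected.

Concentrations are never recovery-corrected by default (reported values
stay raw); an optional ``100/recovery`` correction is available for
sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import PesticidePanel, ResidueSeries

__all__ = [
    "QCConfig",
    "QCReport",
    "assess_recovery",
    "mask_excluded",
    "censor_below_loq",
    "apply_recovery_correction",
]

#: per-analyte recovery statuses
STATUSES = ("pass", "flag_low", "flag_high", "exclude")


@dataclass(frozen=True)
class QCConfig:
    """Recovery acceptance band and censoring rule.

    Defaults: recoveries in [30, 160]% pass, below 10% exclude, anything
    else in between (or above) is flagged but retained.
    """

    recovery_accept_lo: float = 30.0
    recovery_accept_hi: float = 160.0
    recovery_exclude_below: float = 10.0
    censor_rule: str = "drop_below_loq"

    def __post_init__(self) -> None:
        if not (0 <= self.recovery_exclude_below <= self.recovery_accept_lo
                <= self.recovery_accept_hi):
            raise ValueError(
                "require 0 <= exclude_below <= accept_lo <= accept_hi")
        if self.censor_rule != "drop_below_loq":
            raise ValueError(f"unknown censor_rule: {self.censor_rule!r}")


@dataclass
class QCReport:
    """Per-analyte recovery status plus a human-readable note."""

    status: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def excluded(self) -> set[str]:
        return {a for a, s in self.status.items() if s == "exclude"}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"status": pd.Series(self.status), "note": pd.Series(self.notes)}
        ).rename_axis("analyte")


def assess_recovery(panel: PesticidePanel, cfg: QCConfig = QCConfig()) -> QCReport:
    """Label every panel analyte by its recovery rate.

    An absent recovery is flagged (``flag_low`` with a note) but never
    excluded, because absence of a QC value is not evidence of failure.
    """
    report = QCReport()
    for e in panel:
        r = e.recovery_pct
        if r is None:
            report.status[e.name] = "flag_low"
            report.notes[e.name] = "no recovery rate determined"
        elif r < cfg.recovery_exclude_below:
            report.status[e.name] = "exclude"
            report.notes[e.name] = (
                f"recovery {r:g}% below exclusion threshold "
                f"{cfg.recovery_exclude_below:g}%; concentrations unreliable"
            )
        elif r < cfg.recovery_accept_lo:
            report.status[e.name] = "flag_low"
            report.notes[e.name] = f"low recovery {r:g}%, values retained"
        elif r > cfg.recovery_accept_hi:
            report.status[e.name] = "flag_high"
            report.notes[e.name] = f"high recovery {r:g}%, values retained"
        else:
            report.status[e.name] = "pass"
            report.notes[e.name] = ""
    return report


def mask_excluded(series: ResidueSeries, report: QCReport) -> ResidueSeries:
    """Mask concentrations of excluded analytes, keeping their detections.

    Masked detections are represented by a ``NaN`` concentration: they
    still count as detection days for run/persistence analysis but carry
    no value into hazard quotients or pooling.
    """
    excluded = report.excluded
    if not excluded:
        return series
    return series.map_concentrations(
        lambda a, c: float("nan") if a in excluded else c)


def censor_below_loq(series: ResidueSeries, panel: PesticidePanel | None = None
                     ) -> ResidueSeries:
    """Left-censor the series at each analyte's LOQ.

    Quantified values ``>= LOQ`` are kept exactly; values below become not
    detected; masked (NaN) detections are untouched.  Idempotent.  Every
    detected analyte must carry an LOQ in the panel (a panel mismatch
    raises ``ValueError`` via the series constructor).
    """
    panel = panel if panel is not None else series.panel

    def rule(a: str, c: float) -> float | None:
        if math.isnan(c):
            return c
        entry = panel.get(a)
        if entry is None:
            raise ValueError(f"analyte {a!r} has no LOQ in panel")
        return c if c >= entry.loq else None

    return series.map_concentrations(rule)


def apply_recovery_correction(series: ResidueSeries,
                              panel: PesticidePanel | None = None
                              ) -> ResidueSeries:
    """Scale concentrations by ``100/recovery`` (sensitivity analysis only).

    Analytes without a recovery rate are left unchanged.  This correction
    is deliberately OFF in the default pipeline: reported residue values
    stay raw, matching common reporting practice for screening studies.
    """
    panel = panel if panel is not None else series.panel

    def rule(a: str, c: float) -> float:
        r = panel[a].recovery_pct
        if r is None or r == 0 or math.isnan(c):
            return c
        return c * 100.0 / r

    return series.map_concentrations(rule)
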