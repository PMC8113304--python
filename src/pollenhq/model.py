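"""Domain types for pesticide panels and daily residue time series.

The data model mirrors a season-long residue monitoring study: a *panel*
describes every analyte the laboratory screened for (class, limit of
quantification, spike recovery, acute oral honey-bee LD50), and a
*residue series* holds one sample per foraging day, each a sparse map
from analyte name to concentration in ng/g pollen.

Censoring convention: an analyte name present in
:attr:`DailySample.concentrations` means "detected"; a finite value is a
quantified concentration, while ``NaN`` marks a detection whose value has
been masked for reliability reasons (see :mod:`pollenhq.qc`).  An absent
key means not detected.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "PesticideProperty",
    "PesticidePanel",
    "DailySample",
    "ResidueSeries",
    "ValidationReport",
    "validate_series",
    "CLASSES",
]

#: Canonical pesticide class names, in reporting order.
CLASSES = ("fungicide", "herbicide", "insecticide")

_CLASS_ALIASES = {
    "f": "fungicide",
    "fungicide": "fungicide",
    "h": "herbicide",
    "herbicide": "herbicide",
    "i": "insecticide",
    "insecticide": "insecticide",
}


def normalize_class(code: str) -> str:
    """Map a class code (``F``/``H``/``I`` or a full word) to its canonical name.

    Raises ``ValueError`` for anything else.
    """
    try:
        return _CLASS_ALIASES[str(code).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown pesticide class code: {code!r}") from None


@dataclass(frozen=True)
class PesticideProperty:
    """Static per-analyte properties.

    Parameters
    ----------
    name:
        Analyte name, unique within a panel.
    pclass:
        One of ``fungicide``, ``herbicide``, ``insecticide``.
    group:
        Chemical group / mode-of-action label (free text).
    application_areas:
        Opaque set of usage-area codes (e.g. ``f`` fruit, ``v`` vegetable,
        ``i.r.`` insect repellent); used only for reporting.
    loq:
        Limit of quantification in ng/g pollen, strictly positive.
    recovery_pct:
        Spike recovery in percent, or ``None`` when not determined.
    ld50_oral:
        Acute oral honey-bee LD50 in μg/bee, or ``None`` when no value is
        available (hazard quotients are then undefined, never zero).
    bee_hazard_b1:
        Regulatory "hazardous to bees" (B1) flag.
    approved_de:
        Whether the substance is approved for application in Germany.
    """

    name: str
    pclass: str
    group: str = ""
    application_areas: frozenset[str] = frozenset()
    loq: float = 1.0
    recovery_pct: float | None = None
    ld50_oral: float | None = None
    bee_hazard_b1: bool = False
    approved_de: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "pclass", normalize_class(self.pclass))
        object.__setattr__(
            self, "application_areas", frozenset(self.application_areas)
        )
        if not self.name:
            raise ValueError("analyte name must be non-empty")
        if not self.loq > 0:
            raise ValueError(f"{self.name}: LOQ must be > 0, got {self.loq}")
        if self.ld50_oral is not None and not self.ld50_oral > 0:
            raise ValueError(
                f"{self.name}: LD50 must be > 0 or absent, got {self.ld50_oral}"
            )
        if self.recovery_pct is not None and self.recovery_pct < 0:
            raise ValueError(f"{self.name}: recovery must be >= 0")


class PesticidePanel:
    """Ordered, name-unique collection of :class:`PesticideProperty`."""

    def __init__(self, entries: Iterable[PesticideProperty]):
        self.entries: list[PesticideProperty] = list(entries)
        self._by_name: dict[str, PesticideProperty] = {}
        for e in self.entries:
            if e.name in self._by_name:
                raise ValueError(f"duplicate analyte name in panel: {e.name!r}")
            self._by_name[e.name] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PesticideProperty]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> PesticideProperty:
        return self._by_name[name]

    def get(self, name: str) -> PesticideProperty | None:
        return self._by_name.get(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def class_counts(self) -> dict[str, int]:
        """Number of analytes per class, always reporting all three classes."""
        counts = {c: 0 for c in CLASSES}
        for e in self.entries:
            counts[e.pclass] += 1
        return counts

    def class_of(self, name: str) -> str:
        return self._by_name[name].pclass

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        c = self.class_counts()
        return (
            f"PesticidePanel({len(self)} analytes: "
            + ", ".join(f"{v} {k}s" for k, v in c.items())
            + ")"
        )


@dataclass
class DailySample:
    """One daily pollen sample.

    ``day_index`` follows the field convention of numbering only foraging
    days (D1, D2, ...); rain days without foraging carry no sample and no
    index.  ``concentrations`` maps analyte name to ng/g pollen; see the
    module docstring for the censoring convention.
    """

    day_index: int
    date: _dt.date
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError(f"day_index must be >= 1, got {self.day_index}")

    def detected(self) -> set[str]:
        """Names of analytes detected in this sample (quantified or masked)."""
        return set(self.concentrations)

    def quantified(self) -> dict[str, float]:
        """Detections with a finite concentration value."""
        return {
            a: c for a, c in self.concentrations.items() if not math.isnan(c)
        }


class ResidueSeries:
    """Ordered daily samples plus the panel they refer to.

    ``missing_days`` records calendar dates without a sample (rain days);
    they are observationally neutral: no detection, but also no gap in a
    detection run.
    """

    def __init__(
        self,
        samples: Iterable[DailySample],
        panel: PesticidePanel,
        missing_days: Iterable[_dt.date] = (),
    ):
        self.samples: list[DailySample] = list(samples)
        self.panel = panel
        self.missing_days: set[_dt.date] = set(missing_days)
        self._check()

    def _check(self) -> None:
        prev_idx, prev_date = 0, None
        for s in self.samples:
            if s.day_index <= prev_idx:
                raise ValueError(
                    f"day_index not strictly increasing at D{s.day_index}"
                )
            if prev_date is not None and s.date <= prev_date:
                raise ValueError(f"dates not strictly increasing at {s.date}")
            prev_idx, prev_date = s.day_index, s.date
            for name in s.concentrations:
                if name not in self.panel:
                    raise ValueError(
                        f"D{s.day_index}: analyte {name!r} not in panel"
                    )
        overlap = self.missing_days & {s.date for s in self.samples}
        if overlap:
            raise ValueError(f"missing_days overlap sample dates: {overlap}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[DailySample]:
        return iter(self.samples)

    @property
    def day_indices(self) -> list[int]:
        return [s.day_index for s in self.samples]

    def analytes_detected(self) -> list[str]:
        """Panel-ordered names of analytes detected at least once."""
        seen: set[str] = set()
        for s in self.samples:
            seen |= s.detected()
        return [n for n in self.panel.names if n in seen]

    # -- conversions --------------------------------------------------------
    def to_frame(self, analytes: Iterable[str] | None = None) -> pd.DataFrame:
        """Wide day × analyte concentration matrix.

        ``NaN`` cells mean *either* not detected or masked; pair with
        :meth:`detection_mask` when the distinction matters.
        """
        cols = list(analytes) if analytes is not None else self.panel.names
        data = {
            a: [s.concentrations.get(a, float("nan")) for s in self.samples]
            for a in cols
        }
        return pd.DataFrame(data, index=pd.Index(self.day_indices, name="day"))

    def detection_mask(self) -> pd.DataFrame:
        """Boolean day × analyte matrix of detections (masked ones included)."""
        return pd.DataFrame(
            {
                a: [a in s.concentrations for s in self.samples]
                for a in self.panel.names
            },
            index=pd.Index(self.day_indices, name="day"),
        )

    def map_concentrations(
        self, fn, drop_nan_keys: bool = False
    ) -> "ResidueSeries":
        """Return a new series with ``fn(analyte, conc) -> conc | None``
        applied per detection; ``None`` removes the detection."""
        new_samples = []
        for s in self.samples:
            conc: dict[str, float] = {}
            for a, c in s.concentrations.items():
                if math.isnan(c) and drop_nan_keys:
                    continue
                v = fn(a, c)
                if v is not None:
                    conc[a] = v
            new_samples.append(DailySample(s.day_index, s.date, conc))
        return ResidueSeries(new_samples, self.panel, self.missing_days)


@dataclass
class ValidationReport:
    """Outcome of structural validation: (locator, message) pairs.

    Empty ``errors`` means the series is accepted; warnings never reject.
    """

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "errors": [list(e) for e in self.errors],
            "warnings": [list(w) for w in self.warnings],
        }


def validate_series(series: ResidueSeries) -> ValidationReport:
    """Check every type invariant of a residue series.

    Structural failures land in ``errors``; concentrations below the
    analyte's LOQ (legal before censoring, impossible after) produce
    warnings so that an uncensored matrix still validates.
    """
    report = ValidationReport()
    seen_idx: set[int] = set()
    prev_idx = 0
    for s in series.samples:
        loc = f"D{s.day_index}"
        if s.day_index in seen_idx:
            report.errors.append((loc, "duplicate day_index"))
        elif s.day_index < prev_idx:
            report.errors.append((loc, "day_index not increasing"))
        seen_idx.add(s.day_index)
        prev_idx = max(prev_idx, s.day_index)
        for a, c in s.concentrations.items():
            if a not in series.panel:
                report.errors.append((loc, f"analyte {a!r} not in panel"))
                continue
            if math.isnan(c):
                continue
            if c < 0:
                report.errors.append((loc, f"{a}: negative concentration {c}"))
            elif c < series.panel[a].loq:
                report.warnings.append(
                    (loc, f"{a}: concentration {c} below LOQ "
                          f"{series.panel[a].loq} (pre-censoring)")
                )
    if series.missing_days & {s.date for s in series.samples}:
        report.errors.append(("series", "missing_days overlap sample dates"))
    return report
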