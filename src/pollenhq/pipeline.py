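"""Single-command pipeline: QC → hazard → temporal → pooling.

A :class:`RunConfig` (usually parsed from one YAML file) names the
inputs — a pesticide panel plus either a residue matrix on disk or a
synthetic-season specification — and every analysis parameter.  The
stage order is fixed:

1. recovery screening and masking of unreliable analytes,
2. LOQ censoring,
3. hazard-quotient scoring (per-analyte and per-day tables),
4. detection runs and co-application scores,
5. pooling/dilution report,
6. a machine-readable summary of headline counts.

Outputs are plain delimited text with fixed names and column orders so
runs can be diffed; the same config and seed always produce identical
bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import datasets, hazard, pooling, qc, temporal
from .io import read_pesticide_table, read_residue_matrix, write_residue_matrix
from .model import PesticidePanel, ResidueSeries, validate_series
from .simulate import SeriesSpec, SprayEventSpec, generate_series, paper_like_spec

__all__ = ["RunConfig", "ConfigError", "ReportBundle", "run_pipeline",
           "summarize_counts", "load_config"]

log = logging.getLogger("pollenhq")

#: fixed output filenames of a pipeline run
OUTPUT_FILES = (
    "qc_report.csv", "hazard_per_analyte.csv", "hazard_relevant_days.csv",
    "class_decomposition.csv", "detection_runs.csv", "coapplication.csv",
    "pooling.csv", "summary.json",
)


class ConfigError(ValueError):
    """Invalid run configuration; ``keys`` names the offending entries."""

    def __init__(self, message: str, keys: list[str]):
        super().__init__(f"{message} (keys: {', '.join(keys)})")
        self.keys = keys


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    panel_path: str | None = None          # None -> bundled panel
    matrix_path: str | None = None
    synthetic: dict | str | None = None    # "paper_like" or a SeriesSpec dict
    output_dir: str | None = None
    seed: int = 0
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    hazard: hazard.HazardConfig = field(default_factory=hazard.HazardConfig)
    gap_tolerance: int = 1
    windows: tuple = (10, "calendar_month")
    coapplication_pairs: tuple = ()

    def __post_init__(self) -> None:
        if (self.matrix_path is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of a residue matrix path or a synthetic spec "
                "must be given", ["matrix", "synthetic"])
        if self.gap_tolerance < 0:
            raise ConfigError("gap_tolerance must be >= 0", ["gap_tolerance"])


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping", ["<root>"])
    known = {"panel", "matrix", "synthetic", "output_dir", "seed", "qc",
             "hazard", "gap_tolerance", "windows", "coapplication_pairs"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError("unknown configuration keys", unknown)
    try:
        qc_cfg = qc.QCConfig(**(raw.get("qc") or {}))
        hz_cfg = hazard.HazardConfig(**(raw.get("hazard") or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad qc/hazard section: {exc}", ["qc", "hazard"])
    return RunConfig(
        panel_path=raw.get("panel"),
        matrix_path=raw.get("matrix"),
        synthetic=raw.get("synthetic"),
        output_dir=raw.get("output_dir"),
        seed=int(raw.get("seed", 0)),
        qc=qc_cfg,
        hazard=hz_cfg,
        gap_tolerance=int(raw.get("gap_tolerance", 1)),
        windows=tuple(raw.get("windows", (10, "calendar_month"))),
        coapplication_pairs=tuple(
            tuple(p) for p in raw.get("coapplication_pairs", ())),
    )


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    panel: PesticidePanel
    series: ResidueSeries                 # censored, masked
    qc_report: pd.DataFrame
    hazard_table: hazard.HazardTable
    per_analyte: pd.DataFrame
    relevant_day_table: pd.DataFrame
    class_table: pd.DataFrame
    runs_table: pd.DataFrame
    coapplication_table: pd.DataFrame
    pooling_table: pd.DataFrame
    summary: dict


def _build_synthetic(cfg: RunConfig, panel: PesticidePanel) -> ResidueSeries:
    spec = cfg.synthetic
    if spec == "paper_like" or spec is True:
        series, _ = generate_series(paper_like_spec(cfg.seed, panel))
        return series
    if not isinstance(spec, dict):
        raise ConfigError("synthetic must be 'paper_like' or a mapping",
                          ["synthetic"])
    events = [SprayEventSpec(
        analyte=e["analyte"], event_day=int(e["event_day"]),
        peak_conc=float(e["peak_conc"]),
        rise_days=int(e.get("rise_days", 3)),
        decay_days=int(e.get("decay_days", 7)),
        co_applied=tuple((str(a), float(r))
                         for a, r in e.get("co_applied", ())),
    ) for e in spec.get("events", ())]
    series, _ = generate_series(SeriesSpec(
        n_days=int(spec.get("n_days", 102)),
        panel=panel,
        events=events,
        noise_cv=float(spec.get("noise_cv", 0.1)),
        background_rate=float(spec.get("background_rate", 0.0)),
        rain_days=frozenset(spec.get("rain_days", ())),
        seed=cfg.seed,
    ))
    return series


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run all stages; write the report files only when everything passed."""
    log.info("run config: %s", dataclasses.asdict(cfg))
    panel = (read_pesticide_table(cfg.panel_path) if cfg.panel_path
             else datasets.load_panel())

    if cfg.matrix_path is not None:
        raw = read_residue_matrix(cfg.matrix_path, panel)
        report = validate_series(raw)
        if not report.ok:
            raise ConfigError(
                f"residue matrix failed validation: {report.errors}",
                ["matrix"])
    else:
        raw = _build_synthetic(cfg, panel)

    qc_report = qc.assess_recovery(panel, cfg.qc)
    masked = qc.mask_excluded(raw, qc_report)
    series = qc.censor_below_loq(masked)

    table = hazard.hazard_summary(series, cfg.hazard)
    per_analyte = table.reported_per_analyte().reset_index()

    days = hazard.relevant_days(table)
    contrib = table.contributions.loc[days]
    rel_rows = []
    for d in days:
        row = contrib.loc[d].dropna()
        rel_rows.append({
            "day": d,
            "n_detects": int(series.detection_mask().loc[d].sum()),
            "tphq": table.tphq.loc[d],
            "total_conc": float(series.to_frame().loc[d].sum(skipna=True)),
            "contributions": "; ".join(
                f"{a}={hazard.round_sigfigs(v, cfg.hazard.report_sigfigs)}"
                for a, v in row.sort_values(ascending=False).items()),
        })
    relevant_day_table = pd.DataFrame(
        rel_rows, columns=["day", "n_detects", "tphq", "total_conc",
                           "contributions"])

    class_table = hazard.class_decomposition(table).reset_index()

    run_rows = []
    for a in panel.names:
        for r in temporal.detect_runs(series, a, cfg.gap_tolerance):
            run_rows.append(dataclasses.asdict(r))
    runs_table = pd.DataFrame(run_rows, columns=[
        f.name for f in dataclasses.fields(temporal.DetectionRun)])

    coapp = temporal.coapplication_table(
        series, list(cfg.coapplication_pairs))

    pool_table = pooling.dilution_report(
        series, analytes=series.analytes_detected(),
        windows=list(cfg.windows))

    counts_per_day, day_summary = temporal.residues_per_day(series)
    summary = {
        "seed": cfg.seed,
        "n_samples": len(series),
        "n_panel_analytes": len(panel),
        "n_analytes_detected": len(series.analytes_detected()),
        "class_counts_detected": {
            c: sum(1 for a in series.analytes_detected()
                   if panel.class_of(a) == c)
            for c in ("fungicide", "herbicide", "insecticide")},
        "samples_without_residues": day_summary["days_without_residues"],
        "median_residues_per_day": day_summary["median"],
        "max_residues_per_day": day_summary["max"],
        "n_relevant_days": len(days),
        "relevant_days": [int(d) for d in days],
        "excluded_analytes": sorted(qc_report.excluded),
        "undefined_ld50_analytes": sorted(table.undefined_analytes),
    }

    bundle = ReportBundle(
        panel=panel, series=series, qc_report=qc_report.to_frame(),
        hazard_table=table, per_analyte=per_analyte,
        relevant_day_table=relevant_day_table, class_table=class_table,
        runs_table=runs_table, coapplication_table=coapp,
        pooling_table=pool_table, summary=summary)

    if cfg.output_dir:
        _write_bundle(bundle, series, Path(cfg.output_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, series: ResidueSeries,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.qc_report.to_csv(outdir / "qc_report.csv")
    bundle.per_analyte.to_csv(outdir / "hazard_per_analyte.csv", index=False)
    bundle.relevant_day_table.to_csv(
        outdir / "hazard_relevant_days.csv", index=False)
    bundle.class_table.to_csv(outdir / "class_decomposition.csv", index=False)
    bundle.runs_table.to_csv(outdir / "detection_runs.csv", index=False)
    bundle.coapplication_table.to_csv(outdir / "coapplication.csv", index=False)
    bundle.pooling_table.to_csv(outdir / "pooling.csv", index=False)
    write_residue_matrix(series, outdir / "residue_matrix.csv")
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
    log.info("wrote report bundle to %s", outdir)


def summarize_counts(bundle: ReportBundle) -> dict:
    """Recompute headline counts from the bundle's own tables (not cached).

    Cross-checks the stored summary: analytes detected, samples without
    residues, relevant days, and the class breakdown of detections.
    """
    mask = bundle.series.detection_mask()
    detected = [a for a in mask.columns if mask[a].any()]
    return {
        "n_analytes_detected": len(detected),
        "class_counts_detected": {
            c: sum(1 for a in detected if bundle.panel.class_of(a) == c)
            for c in ("fungicide", "herbicide", "insecticide")},
        "samples_without_residues": int((mask.sum(axis=1) == 0).sum()),
        "n_relevant_days": int(len(bundle.relevant_day_table)),
    }
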